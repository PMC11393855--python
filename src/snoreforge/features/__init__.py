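"""Six-domain acoustic feature extraction.

Every clip is summarized by named features tagged with the domain that
produced them (``time``, ``freq``, ``dwt``, ``sparse``, ``eigen``,
``cepstral``); names follow the ``domain.feature.stat`` scheme so that
binary selection masks keep stable semantics across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..audio import AudioClip, frame_signal
from .time_domain import (zero_crossing_rate, modified_zcr, short_time_energy,
                          time_domain_features)
from .spectral import (spectral_shape_features, ltas_features, tonality_features,
                       autoregressive_features)
from .transforms import dwt_features, sparse_features, eigen_features, omp_decompose, dct_dictionary
from .cepstral import cepstral_features, mfcc, gtcc, lpcc

DOMAINS = ("time", "freq", "dwt", "sparse", "eigen", "cepstral")

__all__ = [
    "DOMAINS", "FeatureVector", "FeatureTable", "extract_clip_features",
    "extract_domain", "extract_features",
    "zero_crossing_rate", "modified_zcr", "short_time_energy",
    "time_domain_features", "spectral_shape_features", "ltas_features",
    "tonality_features", "autoregressive_features", "dwt_features",
    "sparse_features", "eigen_features", "omp_decompose", "dct_dictionary",
    "cepstral_features", "mfcc", "gtcc", "lpcc",
]


@dataclass
class FeatureVector:
    """Named per-clip feature values."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")


@dataclass
class FeatureTable:
    """Per-clip feature matrix with labels; rows share one column order."""

    names: list[str]
    X: np.ndarray  # (n_clips, n_features)
    labels: np.ndarray
    clip_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("feature matrix does not match column names")
        if not self.clip_ids:
            self.clip_ids = [f"clip{i:04d}" for i in range(self.X.shape[0])]

    @property
    def n_features(self) -> int:
        return len(self.names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "label", self.labels)
        df.insert(0, "clip_id", self.clip_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("clip_id", "label")]
        return cls(names=names, X=df[names].to_numpy(dtype=np.float64),
                   labels=df["label"].to_numpy(), clip_ids=df["clip_id"].astype(str).tolist())

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"columns": self.names}, fh, indent=2)

    def select(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, b in zip(self.names, mask) if b]
        return FeatureTable(names=names, X=self.X[:, mask], labels=self.labels,
                            clip_ids=list(self.clip_ids))


def extract_clip_features(clip: AudioClip, domain: str, *, frame_ms: float = 25.0,
                          hop_ms: float = 10.0) -> FeatureVector:
    """Feature vector for one clip in one domain."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    if domain in ("dwt", "sparse"):
        frames = None
    else:
        frames = frame_signal(clip, frame_ms, hop_ms, "hamming")
    if domain == "time":
        names, values = time_domain_features(clip, frames)
    elif domain == "freq":
        parts = [spectral_shape_features(frames), ltas_features(frames),
                 tonality_features(clip, frames), autoregressive_features(frames)]
        names = sum((p[0] for p in parts), [])
        values = np.concatenate([p[1] for p in parts])
    elif domain == "dwt":
        names, values = dwt_features(clip)
    elif domain == "sparse":
        names, values = sparse_features(clip)
    elif domain == "eigen":
        names, values = eigen_features(frames)
    else:
        names, values = cepstral_features(frames)
    return FeatureVector(names=names, values=values)


def extract_domain(clips: list[AudioClip], domain: str, *, frame_ms: float = 25.0,
                   hop_ms: float = 10.0) -> FeatureTable:
    """One-domain feature table for a list of clips (stable column order)."""
    if not clips:
        raise ValueError("clip list is empty")
    vecs = [extract_clip_features(c, domain, frame_ms=frame_ms, hop_ms=hop_ms) for c in clips]
    names = vecs[0].names
    for v in vecs[1:]:
        if v.names != names:  # pragma: no cover - extractor guarantees stability
            raise RuntimeError("inconsistent feature columns across clips")
    return FeatureTable(names=names, X=np.vstack([v.values for v in vecs]),
                        labels=np.array([c.label for c in clips]),
                        clip_ids=[c.clip_id for c in clips])


def extract_features(clips: list[AudioClip], domains: list[str] | tuple[str, ...],
                     **kw) -> FeatureTable:
    """Concatenate feature tables over several domains."""
    tables = [extract_domain(clips, d, **kw) for d in domains]
    names = sum((t.names for t in tables), [])
    X = np.hstack([t.X for t in tables])
    return FeatureTable(names=names, X=X, labels=tables[0].labels,
                        clip_ids=tables[0].clip_ids)
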