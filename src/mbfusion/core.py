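"""Shared containers for multi-block studies.

A *block* is one analytical platform's samples × features matrix
(LC-MS, GC-MS, NMR buckets, MIR grid points).  All blocks of a study
share the same sample index; the manifest carries each sample's origin
label and its role (``model`` — used to build classifiers — or
``external`` — held out for external validation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLATFORMS = ("LCMS", "GCMS", "NMR", "MIR")
ROLES = ("model", "external")


@dataclass
class FeatureBlock:
    """One platform's samples × features table.

    Parameters
    ----------
    platform : str
        Platform tag, e.g. ``"LCMS"`` or ``"NMR"``.
    data : pandas.DataFrame
        Rows indexed by sample id, columns are feature ids.
    coords : pandas.Series, optional
        Per-feature axis coordinate (ppm for NMR buckets, cm⁻¹ for MIR
        grid points), indexed like ``data.columns``.
    """

    platform: str
    data: pd.DataFrame
    coords: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a DataFrame")
        if self.data.columns.duplicated().any():
            raise ValueError(f"{self.platform}: duplicated feature ids")
        if self.coords is not None:
            self.coords = pd.Series(self.coords)
            if not self.coords.index.equals(self.data.columns):
                raise ValueError(f"{self.platform}: coords do not match columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def restrict(self, sample_ids: Sequence[str]) -> "FeatureBlock":
        """Row subset in the given order."""
        return FeatureBlock(self.platform, self.data.loc[list(sample_ids)], self.coords)

    def select(self, feature_ids: Sequence[str]) -> "FeatureBlock":
        """Column subset in the given order."""
        feature_ids = list(feature_ids)
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"{self.platform}: unknown features {missing[:5]}")
        coords = self.coords.loc[feature_ids] if self.coords is not None else None
        return FeatureBlock(self.platform, self.data[feature_ids], coords)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, platform: str, path: str | Path) -> "FeatureBlock":
        data = pd.read_csv(path, index_col="sample_id")
        data.index.name = None
        return cls(platform, data)


@dataclass
class SampleManifest:
    """Sample ids with origin labels and model/external role."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        need = {"sample_id", "group", "role"}
        if not need.issubset(self.frame.columns):
            raise ValueError(f"manifest needs columns {sorted(need)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids")
        bad = set(self.frame["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles {bad}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def model_ids(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["role"] == "model", "sample_id"])

    @property
    def external_ids(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["role"] == "external", "sample_id"])

    @property
    def groups(self) -> pd.Series:
        """Group label per sample, indexed by sample id."""
        return self.frame.set_index("sample_id")["group"]

    @property
    def model_groups(self) -> list[str]:
        f = self.frame
        return sorted(f.loc[f["role"] == "model", "group"].unique())

    @property
    def external_groups(self) -> list[str]:
        f = self.frame
        return sorted(f.loc[f["role"] == "external", "group"].unique())

    @classmethod
    def from_counts(
        cls,
        model_groups: Iterable[tuple[str, int]],
        external_groups: Iterable[tuple[str, int]] = (),
    ) -> "SampleManifest":
        rows = []
        for role, spec in (("model", model_groups), ("external", external_groups)):
            for label, n in spec:
                for i in range(int(n)):
                    rows.append((f"{label}_{i + 1:02d}", label, role))
        return cls(pd.DataFrame(rows, columns=["sample_id", "group", "role"]))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleManifest":
        return cls(pd.read_csv(path))


def check_aligned(blocks: Sequence[FeatureBlock]) -> pd.Index:
    """Assert identical sample ordering across blocks; return the index."""
    if not blocks:
        raise ValueError("no blocks given")
    idx = blocks[0].sample_ids
    for b in blocks[1:]:
        if not b.sample_ids.equals(idx):
            raise ValueError(
                f"sample alignment mismatch between {blocks[0].platform} and {b.platform}"
            )
    return idx


def child_seed(seed: int, key: str) -> int:
    """Platform-keyed child seed: stable fan-out from one global seed.

    Keyed by name (CRC32), not by position, so adding a block never
    perturbs the streams of earlier blocks.
    """
    import zlib

    return int((int(seed) * 100003 + zlib.crc32(key.encode())) % (2**31))
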