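"""Core in-memory containers shared across the pipeline.

Genotypes are stored as an individuals x sites matrix of alternate-allele
dosages (0, 1, 2) with -1 marking a missing call.  All downstream modules
(filtering, kinship, diversity, divergence, AMOVA, RDA) operate on these
containers rather than on files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

MISSING: int = -1


@dataclass
class GenotypeDataset:
    """Biallelic SNP calls with sample metadata.

    Attributes
    ----------
    calls:
        ``(n_individuals, n_sites)`` int8 array of alternate-allele dosages
        in {0, 1, 2}; missing calls are ``-1``.
    sample_ids, locality_labels, group_labels:
        Length ``n_individuals`` arrays.  ``group_labels`` may be empty when
        no higher-level grouping is defined.
    coordinates:
        ``(n_individuals, 2)`` array of (x, y) positions in arbitrary
        planar units (one point per individual; individuals from the same
        locality may share a point).
    site_ids:
        Length ``n_sites`` array of site identifiers.
    truth:
        Optional record of simulation ground truth (only present on
        simulated datasets).
    """

    calls: np.ndarray
    sample_ids: np.ndarray
    locality_labels: np.ndarray
    group_labels: np.ndarray
    coordinates: np.ndarray
    site_ids: np.ndarray
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids)
        self.locality_labels = np.asarray(self.locality_labels)
        self.group_labels = np.asarray(self.group_labels)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.site_ids = np.asarray(self.site_ids)
        n, m = self.calls.shape
        if self.sample_ids.shape[0] != n:
            raise ValueError("sample_ids length does not match calls rows")
        if self.locality_labels.shape[0] != n:
            raise ValueError("locality_labels length does not match calls rows")
        if self.group_labels.size and self.group_labels.shape[0] != n:
            raise ValueError("group_labels length does not match calls rows")
        if self.site_ids.shape[0] != m:
            raise ValueError("site_ids length does not match calls columns")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def take_individuals(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to the given individual indices (order preserved)."""
        index = np.asarray(index)
        return replace(
            self,
            calls=self.calls[index],
            sample_ids=self.sample_ids[index],
            locality_labels=self.locality_labels[index],
            group_labels=self.group_labels[index] if self.group_labels.size else self.group_labels,
            coordinates=self.coordinates[index] if self.coordinates.size else self.coordinates,
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        truth = None
        if self.truth is not None:
            truth = dict(self.truth)
            for key in ("p_ancestral", "p_group", "p_locality"):
                if key in truth:
                    arr = np.asarray(truth[key])
                    truth[key] = arr[..., index]
            if "cline_loci" in truth:
                old = np.asarray(truth["cline_loci"])
                pos = {s: j for j, s in enumerate(index.tolist())}
                truth["cline_loci"] = np.array(
                    [pos[s] for s in old.tolist() if s in pos], dtype=int
                )
        return replace(self, calls=self.calls[:, index], site_ids=self.site_ids[index], truth=truth)


@dataclass
class AlleleDepthTable:
    """Per-genotype reference and alternate read counts, aligned to calls."""

    ref_reads: np.ndarray
    alt_reads: np.ndarray
    ploidy_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ref_reads = np.asarray(self.ref_reads, dtype=np.int32)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int32)
        if self.ref_reads.shape != self.alt_reads.shape:
            raise ValueError("ref_reads and alt_reads shapes differ")
        if (self.ref_reads < 0).any() or (self.alt_reads < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads

    def take_individuals(self, index: np.ndarray) -> "AlleleDepthTable":
        pt = self.ploidy_truth[index] if self.ploidy_truth is not None else None
        return AlleleDepthTable(self.ref_reads[index], self.alt_reads[index], pt)

    def take_sites(self, index: np.ndarray) -> "AlleleDepthTable":
        return AlleleDepthTable(
            self.ref_reads[:, index], self.alt_reads[:, index], self.ploidy_truth
        )


@dataclass
class LeafTable:
    """Leaf measurements: one row per leaf, with sample/locality/group labels."""

    table: Any  # pandas.DataFrame with columns L, W, WL, sample, locality, group

    def __post_init__(self) -> None:
        needed = {"L", "W", "WL", "sample", "locality", "group"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValueError(f"leaf table missing columns: {sorted(missing)}")


@dataclass
class EnvTable:
    """Per-locality environment values plus locality coordinates."""

    table: Any  # pandas.DataFrame with columns locality, x, y, env...
    env_columns: list[str] = field(default_factory=list)
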