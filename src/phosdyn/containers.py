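"""Core in-memory containers shared across pipeline stages.

The central object is :class:`AbundanceMatrix`: a complete (no missing
values) nonnegative feature x sample table with a sample design
(time point, biological replicate, dataset) and per-feature metadata
(protein accession, site position, residue, +/-10 flank for
phosphopeptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical 20-letter amino-acid alphabet (alphabetical)
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: terminal padding character used to keep flanks exactly 21 residues;
#: never counted, never scored
PAD = "_"

SAMPLE_COLUMNS = ("time_min", "replicate", "dataset")


@dataclass
class AbundanceMatrix:
    """Nonnegative feature x sample abundance table with design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.
    sample_meta
        DataFrame indexed by sample id with columns ``time_min``,
        ``replicate`` and ``dataset``; row order matches ``values`` columns.
    feature_meta
        Optional DataFrame indexed by feature id (accession, position,
        residue, flank for phosphopeptides; accession for proteins).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        if set(self.sample_meta.index) != set(self.values.columns):
            raise ValueError("sample_meta index does not match value columns")
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.feature_meta is not None:
            if not self.values.index.equals(self.feature_meta.index):
                self.feature_meta = self.feature_meta.loc[self.values.index]
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("abundance matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_at(self, *, time_min=None, replicate=None, dataset=None) -> list:
        """Sample ids matching the given design coordinates."""
        mask = pd.Series(True, index=self.sample_meta.index)
        if time_min is not None:
            mask &= self.sample_meta["time_min"] == time_min
        if replicate is not None:
            mask &= self.sample_meta["replicate"] == replicate
        if dataset is not None:
            mask &= self.sample_meta["dataset"] == dataset
        return list(self.sample_meta.index[mask])

    def with_values(self, values: pd.DataFrame) -> "AbundanceMatrix":
        """Copy of self with a replacement value table (same design)."""
        return AbundanceMatrix(values, self.sample_meta.copy(),
                               None if self.feature_meta is None
                               else self.feature_meta.copy())

    def copy(self) -> "AbundanceMatrix":
        return self.with_values(self.values.copy())

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, values_path, sample_path, feature_path=None) -> None:
        self.values.rename_axis("feature_id").to_csv(values_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(sample_path, sep="\t")
        if feature_path is not None and self.feature_meta is not None:
            self.feature_meta.rename_axis("feature_id").to_csv(
                feature_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, sample_path,
                 feature_path=None) -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
        sample_meta = pd.read_csv(sample_path, sep="\t", index_col="sample_id")
        feature_meta = None
        if feature_path is not None:
            feature_meta = pd.read_csv(feature_path, sep="\t",
                                       index_col="feature_id")
        return cls(values, sample_meta, feature_meta)


@dataclass
class ProteinRecord:
    """A protein sequence with a per-residue disorder track in [0, 1]."""

    accession: str
    sequence: str
    disorder: np.ndarray

    def __post_init__(self) -> None:
        self.disorder = np.asarray(self.disorder, dtype=float)
        if len(self.sequence) == 0:
            raise ValueError(f"{self.accession}: empty sequence")
        if len(self.disorder) != len(self.sequence):
            raise ValueError(
                f"{self.accession}: disorder track length "
                f"{len(self.disorder)} != sequence length {len(self.sequence)}")
        if ((self.disorder < 0) | (self.disorder > 1)).any():
            raise ValueError(f"{self.accession}: disorder scores outside [0,1]")


def extract_flank(sequence: str, position: int, width: int = 10) -> str:
    """Return the +/-``width`` flank around a 1-based site position.

    Positions beyond the protein termini are padded with ``_`` so the
    result always has length ``2 * width + 1``.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence "
                         f"of length {len(sequence)}")
    i = position - 1
    left = sequence[max(0, i - width):i].rjust(width, PAD)
    right = sequence[i + 1:i + 1 + width].ljust(width, PAD)
    return left + sequence[i] + right


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``sites`` has one row per phosphosite (site_id, true_kinase,
    kinetic_class, true_Vm, true_K, baseline, decrease_rate);
    ``loading_factors`` is a per-sample multiplier series;
    ``replicate_offsets`` a site x replicate multiplicative batch table.
    """

    sites: pd.DataFrame
    loading_factors: pd.Series
    replicate_offsets: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.sites.index.duplicated().any():
            raise ValueError("duplicate site ids in truth table")
        kin = self.sites["kinetic_class"].isin(("fast", "slow"))
        if (self.sites.loc[kin, "true_K"] <= 0).any():
            raise ValueError("true_K must be > 0 for fast/slow sites")
        if (self.loading_factors <= 0).any():
            raise ValueError("loading factors must be positive")
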