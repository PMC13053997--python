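"""Core data containers for the triage pipeline.

The central object is :class:`AbundanceMatrix`: a protein-group x sample
intensity table with an explicit missingness mask and a ``scale_state`` tag
that records where the matrix sits in the five-step processing pipeline
(log2 -> quantile normalization -> batch correction -> imputation -> z-score).
Operations that require a particular state refuse to run out of order, which
turns silent pipeline misuse into loud errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Orderly progression of processing states. Operations may only move the
#: matrix forward through this list.
SCALE_STATES = ("raw", "log2", "normalized", "batch_corrected", "imputed", "zscored")

GROUPS = ("G1", "G2", "G3")
#: G1 = FIT-positive, colonoscopy-negative (false positive); G2 = advanced
#: adenoma; G3 = colorectal cancer. Cases are G2 u G3 throughout.
CASE_GROUPS = ("G2", "G3")
CONTROL_GROUP = "G1"


class PipelineStateError(RuntimeError):
    """Raised when an operation is applied to a matrix in the wrong state."""


@dataclass
class AbundanceMatrix:
    """Protein-group x sample abundance matrix with missingness mask.

    Parameters
    ----------
    values
        DataFrame, rows = protein-group ids, columns = sample ids. Missing
        cells are NaN.
    mask
        Boolean DataFrame congruent with ``values``; True marks a missing
        (not-quantified) cell. Kept for provenance even after imputation.
    scale_state
        One of :data:`SCALE_STATES`.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share index and columns")

    # -- convenience accessors -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed_fraction(self) -> float:
        """Overall quantification rate (fraction of non-missing cells)."""
        return float(1.0 - self.mask.to_numpy().mean())

    def require_state(self, *allowed: str) -> None:
        if self.scale_state not in allowed:
            raise PipelineStateError(
                f"operation requires scale_state in {allowed}, got {self.scale_state!r}"
            )

    def advance(self, values: pd.DataFrame, new_state: str) -> "AbundanceMatrix":
        """Return a copy with new values and a forward state transition."""
        if SCALE_STATES.index(new_state) < SCALE_STATES.index(self.scale_state):
            raise PipelineStateError(
                f"cannot move from {self.scale_state!r} back to {new_state!r}"
            )
        return AbundanceMatrix(values=values, mask=self.mask.copy(), scale_state=new_state)

    @classmethod
    def from_values(cls, values: pd.DataFrame, scale_state: str = "raw") -> "AbundanceMatrix":
        """Build a matrix from a DataFrame, inferring the mask from NaNs."""
        return cls(values=values, mask=values.isna(), scale_state=scale_state)


def make_sample_meta(sample_ids, groups, batches) -> pd.DataFrame:
    """Assemble the per-sample metadata table (group, batch)."""
    meta = pd.DataFrame({"group": list(groups), "batch": list(batches)}, index=pd.Index(sample_ids, name="sample_id"))
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown diagnostic groups: {sorted(bad)}")
    return meta


def make_protein_meta(protein_ids, species, excluded=None) -> pd.DataFrame:
    """Assemble the per-protein metadata table (species inference, exclusion flag)."""
    idx = pd.Index(protein_ids, name="protein_id")
    if excluded is None:
        excluded = np.zeros(len(idx), dtype=bool)
    return pd.DataFrame({"species": list(species), "excluded": np.asarray(excluded, dtype=bool)}, index=idx)


def case_control_labels(sample_meta: pd.DataFrame, case_groups=CASE_GROUPS, control_group=CONTROL_GROUP) -> pd.Series:
    """Binary labels: 1 for case groups (G2/G3), 0 for the control group."""
    grp = sample_meta["group"]
    present = set(grp)
    for g in tuple(case_groups) + (control_group,):
        if g not in present:
            raise ValueError(f"group {g!r} absent from sample metadata")
    return (grp.isin(case_groups)).astype(int)
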