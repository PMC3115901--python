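"""Core data containers shared across the pipeline.

A :class:`GenotypeMatrix` holds counted-allele dosages (0, 1, 2, or
:data:`MISSING`) for a panel of biallelic SNPs, together with the panel
annotation (gene, chromosome, counted allele).  A :class:`PhenotypeTable`
holds the continuous indicator traits (e.g. diastolic and systolic blood
pressure) and the covariates that drive class membership.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype dosage.
MISSING: int = -1

PANEL_COLUMNS = ("snp_id", "gene", "chromosome", "counted_allele")


def _check_unique(values, what: str) -> None:
    values = list(values)
    if len(set(values)) != len(values):
        dupes = sorted({v for v in values if list(values).count(v) > 1})
        raise ValueError(f"duplicated {what}: {dupes}")


@dataclasses.dataclass
class GenotypeMatrix:
    """Subjects x SNPs counted-allele dosage matrix with panel annotation.

    Parameters
    ----------
    subjects
        Subject identifiers, one per row of ``dosages``.
    panel
        DataFrame indexed by ``snp_id`` with columns ``gene``,
        ``chromosome`` and ``counted_allele``; one row per column of
        ``dosages``, in column order.
    dosages
        Integer array of shape ``(n_subjects, n_snps)`` with values in
        ``{0, 1, 2, MISSING}``.
    """

    subjects: list[str]
    panel: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        if self.dosages.shape[0] != len(self.subjects):
            raise ValueError("dosage rows do not match the subject list")
        if self.dosages.shape[1] != len(self.panel):
            raise ValueError("dosage columns do not match the panel")
        _check_unique(self.subjects, "subject_id")
        _check_unique(self.panel.index, "snp_id")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING (-1)")
        for col in ("gene",):
            if col not in self.panel.columns:
                raise ValueError(f"panel must carry a '{col}' column")

    # -- basic views ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.panel.index)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP."""
        j = self.panel.index.get_loc(snp_id)
        return self.dosages[:, j]

    def gene_of(self, snp_id: str) -> str:
        return str(self.panel.loc[snp_id, "gene"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=pd.Index(self.subjects, name="subject_id"),
                            columns=self.panel.index)

    # -- subsetting ----------------------------------------------------
    def take_subjects(self, mask_or_ids) -> "GenotypeMatrix":
        """Row subset by boolean mask or list of subject ids (reordering)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {s: i for i, s in enumerate(self.subjects)}
            missing = [s for s in mask_or_ids if s not in pos]
            if missing:
                raise KeyError(f"subjects absent from genotype matrix: {missing[:5]}")
            idx = np.array([pos[s] for s in mask_or_ids], dtype=int)
        return GenotypeMatrix([self.subjects[i] for i in idx], self.panel,
                              self.dosages[idx])


@dataclasses.dataclass
class PhenotypeTable:
    """Indicators *y* and covariates *z* per subject.

    ``data`` is indexed by ``subject_id``; ``indicators`` and
    ``covariates`` name its columns.  Missing entries stay as NaN and are
    dropped complete-case by each consumer.
    """

    data: pd.DataFrame
    indicators: list[str]
    covariates: list[str]

    def __post_init__(self) -> None:
        if len(self.indicators) < 1:
            raise ValueError("need at least one indicator column")
        _check_unique(self.data.index, "subject_id")
        absent = [c for c in (*self.indicators, *self.covariates)
                  if c not in self.data.columns]
        if absent:
            raise ValueError(f"columns absent from phenotype table: {absent}")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "subject_id"

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def indicator_matrix(self) -> np.ndarray:
        return self.data[self.indicators].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((len(self.data), 0))
        return self.data[self.covariates].to_numpy(dtype=float)

    def complete_cases(self) -> np.ndarray:
        """Boolean mask of rows with no missing indicator/covariate."""
        cols = [*self.indicators, *self.covariates]
        return ~self.data[cols].isna().any(axis=1).to_numpy()
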