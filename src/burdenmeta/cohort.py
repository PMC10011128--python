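"""In-memory cohort container shared by every pipeline stage.

Genotypes are held as a dense ``samples x variants`` allele-dosage matrix
(int8; 0/1/2 copies of the alternate allele, -1 for missing) with a parallel
read-depth matrix. Sample, variant and gene-panel metadata live in indexed
pandas DataFrames so stages can subset consistently by id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for a no-call


@dataclass
class TruthRecord:
    """Generator ground truth, carried alongside simulated cohorts."""

    true_or: float = 1.0
    enriched_genes: frozenset = frozenset()
    planted_outlier_ids: frozenset = frozenset()
    related_pairs: list = field(default_factory=list)  # (id_a, id_b, kinship class)


@dataclass
class CohortBundle:
    """Genotypes plus sample/variant/panel metadata.

    Attributes
    ----------
    dosages : int8 array, shape (n_samples, n_variants)
        Alternate-allele dosage per call; ``MISSING`` (-1) marks no-calls.
    depths : int32 array, same shape
        Read depth per call.
    samples : DataFrame indexed by sample id
        Must carry ``phenotype`` (0 control / 1 case); simulated cohorts add
        ``population`` and the nine per-sample QC metrics.
    variants : DataFrame indexed by variant id
        Columns ``chrom, pos, ref, alt, gene, consequence, mpc`` (annotation
        adds ``variant_class``). Row order matches dosage columns.
    panel : DataFrame indexed by gene
        Columns ``pli`` and boolean ``constrained``.
    truth : TruthRecord or None
        Present for simulated cohorts only.
    """

    dosages: np.ndarray
    depths: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame
    panel: pd.DataFrame
    truth: TruthRecord | None = None

    def __post_init__(self):
        ns, nv = self.dosages.shape
        if self.depths.shape != (ns, nv):
            raise ValueError("dosage and depth matrices must share a shape")
        if len(self.samples) != ns:
            raise ValueError("sample table does not match genotype rows")
        if len(self.variants) != nv:
            raise ValueError("variant table does not match genotype columns")
        if not self.variants["gene"].isin(self.panel.index).all():
            missing = set(self.variants["gene"]) - set(self.panel.index)
            raise ValueError(f"variants annotated to genes absent from panel: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def subset_samples(self, ids) -> "CohortBundle":
        """Return a new bundle restricted to ``ids`` (order preserved as given)."""
        idx = self.samples.index.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown sample id in subset")
        return replace(
            self,
            dosages=self.dosages[idx],
            depths=self.depths[idx],
            samples=self.samples.iloc[idx],
        )

    def subset_variants(self, ids) -> "CohortBundle":
        idx = self.variants.index.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            raise KeyError("unknown variant id in subset")
        return replace(
            self,
            dosages=self.dosages[:, idx],
            depths=self.depths[:, idx],
            variants=self.variants.iloc[idx],
        )

    def allele_counts(self) -> pd.DataFrame:
        """Per-variant alt-allele count and total called alleles (missing excluded)."""
        called = self.dosages != MISSING
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return pd.DataFrame({"alt_count": alt, "total_alleles": total}, index=self.variants.index)
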