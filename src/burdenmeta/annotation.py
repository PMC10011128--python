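"""Variant class assignment and rare-variant definitions.

Coding variants fall into three broad types: protein-truncating variants
(PTVs: stop gained, frameshift, essential splice donor/acceptor), missense
and synonymous. Missense variants are tiered by the MPC constraint score
(tier 1: MPC > 3; tier 2: MPC in [2, 3]; nondamaging: MPC < 2). Rarity is
judged on the minor allele, either by count (MAC <= 5, the default used in
ancestry-combined analyses) or by frequency (MAF < 0.1%, used within
ancestry strata to preserve power).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PTV_TERMS = frozenset(
    {"stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"}
)
MISSENSE_TERMS = frozenset({"missense_variant"})
SYNONYMOUS_TERMS = frozenset({"synonymous_variant"})

#: most-damaging-first order used when a variant carries several annotations
SEVERITY_ORDER = ("PTV", "missense", "synonymous", "other")

CLASS_NAMES = (
    "PTV",
    "missense_tier1",
    "missense_tier2",
    "missense_nondamaging",
    "synonymous",
    "other",
)


@dataclass(frozen=True)
class RareVariantConfig:
    """How 'rare' is decided: by minor allele count or minor allele frequency."""

    mode: str = "mac"  # "mac" or "maf"
    mac_max: int = 5
    maf_max: float = 0.001

    def __post_init__(self):
        if self.mode not in ("mac", "maf"):
            raise ValueError(f"mode must be 'mac' or 'maf', got {self.mode!r}")
        if self.mac_max < 1:
            raise ValueError("mac_max must be >= 1")
        if not 0 < self.maf_max < 0.5:
            raise ValueError("maf_max must be in (0, 0.5)")


def classify_consequence(term: str) -> str:
    """Map a consequence term to its broad class stem.

    Unknown terms are logged and classed ``other``.
    """
    if term in PTV_TERMS:
        return "PTV"
    if term in MISSENSE_TERMS:
        return "missense"
    if term in SYNONYMOUS_TERMS:
        return "synonymous"
    known_other = {"intron_variant", "intergenic_variant", "5_prime_UTR_variant",
                   "3_prime_UTR_variant", "upstream_gene_variant", "downstream_gene_variant",
                   "splice_region_variant", "start_lost", "stop_lost", "inframe_deletion",
                   "inframe_insertion"}
    if term not in known_other:
        logger.warning("unknown consequence term %r classed as 'other'", term)
    return "other"


def mpc_tier(mpc: float | None) -> str:
    """Tier a missense variant by MPC.

    Boundary convention: MPC exactly 2 or 3 falls in tier 2 (closed interval).
    A missing score is treated as nondamaging, with a warning, mirroring the
    score's limited transcript coverage.
    """
    if mpc is None or (isinstance(mpc, float) and np.isnan(mpc)):
        logger.warning("missense variant without MPC score treated as nondamaging")
        return "nondamaging"
    if mpc > 3:
        return "tier1"
    if mpc >= 2:
        return "tier2"
    return "nondamaging"


def variant_class(consequence: str, mpc: float | None = None) -> str:
    """Full analysis class for one annotation (PTV / missense tier / synonymous / other)."""
    stem = classify_consequence(consequence)
    if stem == "missense":
        return f"missense_{mpc_tier(mpc)}"
    return stem


def classify_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Add a ``variant_class`` column from ``consequence`` and ``mpc``.

    If the table holds several annotation rows per variant id (index), the
    most damaging one is kept (severity order PTV > missense > synonymous >
    other), matching the canonical-transcript/most-damaging convention.
    """
    out = variants.copy()
    stems = out["consequence"].map(classify_consequence)
    if out.index.has_duplicates:
        rank = stems.map({s: i for i, s in enumerate(SEVERITY_ORDER)}).to_numpy()
        keep = np.zeros(len(out), dtype=bool)
        order = pd.Series(rank, index=np.arange(len(out))).groupby(out.index.to_numpy(), sort=False)
        for _, grp in order:
            keep[grp.idxmin()] = True
        out = out.loc[keep]
        stems = stems.loc[keep]
    mpc = out["mpc"] if "mpc" in out.columns else pd.Series(np.nan, index=out.index)
    classes = []
    for stem, score in zip(stems, mpc):
        classes.append(f"missense_{mpc_tier(score)}" if stem == "missense" else stem)
    out["variant_class"] = classes
    return out


def is_rare(alt_count: int, total_alleles: int, config: RareVariantConfig) -> bool:
    """Whether a variant is rare under ``config``, judged on the minor allele.

    MAC mode uses a closed bound (count <= mac_max); MAF mode a strict one
    (frequency < maf_max).
    """
    if total_alleles <= 0:
        raise ValueError("total called alleles must be positive")
    if not 0 <= alt_count <= total_alleles:
        raise ValueError("alt allele count outside [0, total]")
    minor = min(alt_count, total_alleles - alt_count)
    if config.mode == "mac":
        return minor <= config.mac_max
    return minor / total_alleles < config.maf_max


def rare_mask(alt_counts: np.ndarray, totals: np.ndarray, config: RareVariantConfig) -> np.ndarray:
    """Vectorised :func:`is_rare` over per-variant allele counts."""
    alt = np.asarray(alt_counts)
    tot = np.asarray(totals)
    if (tot <= 0).any():
        raise ValueError("total called alleles must be positive for every variant")
    minor = np.minimum(alt, tot - alt)
    if config.mode == "mac":
        return minor <= config.mac_max
    return minor / tot < config.maf_max
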