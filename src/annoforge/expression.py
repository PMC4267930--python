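"""FDR control, tissue-bias classification and cross-species concordance.

Differential-expression testing itself is upstream of this package: inputs
are per-gene p-values and log2 fold changes for the four tissue contrasts
(gonad vs. same-sex somatic carcass, carcass vs. carcass, gonad vs. gonad).
This module applies the Benjamini-Hochberg step-up rule at FDR <= 0.1,
assigns each significant gene a bias toward its higher-expressed tissue,
and measures how often tissue bias is shared between species across
first-order reciprocal-best-hit orthologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_model import Config, DEFAULT_CONFIG, FormatError
from .orthology import OrthologPair

logger = logging.getLogger("annoforge")

CONTRASTS = (
    "ovary_vs_female_carcass",
    "testes_vs_male_carcass",
    "female_carcass_vs_male_carcass",
    "ovary_vs_testes",
)

BIASES = ("tissue_1", "tissue_2", "none")


@dataclass(frozen=True)
class DECall:
    """One gene's differential-expression result for one tissue contrast."""

    gene_id: str
    contrast: str
    p_value: float
    log2_fold: float
    q_value: Optional[float] = None
    bias: str = "none"
    rejected: bool = False
    tested: bool = True

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.tested and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.bias not in BIASES:
            raise ValueError(f"unknown bias {self.bias!r}")


@dataclass(frozen=True)
class ConcordanceSummary:
    contrast: str
    n_biased_a_with_ortholog: int
    n_same_bias_b: int
    fraction_concordant: float


def bh_fdr(p_values: Mapping[str, float], alpha: float = 0.1
           ) -> dict[str, tuple[float, bool]]:
    """Benjamini-Hochberg step-up: gene -> (q_value, rejected).

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted p-values; rejection at
    q <= alpha.  Deterministic; ties share q-values.
    """
    genes = list(p_values)
    p = np.asarray([p_values[g] for g in genes], dtype=float)
    if p.size == 0:
        return {}
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {g: (float(qv), bool(rj)) for g, qv, rj in zip(genes, q, rejected)}


def classify_bias(call: DECall, alpha: float = 0.1) -> DECall:
    """Fill the bias field from a q-valued call.

    Significant genes are biased toward the higher-expressed tissue (the
    sign of log2_fold, tissue_1 when positive); non-significant genes and
    the degenerate fold-zero case carry no bias.
    """
    if call.q_value is None:
        raise ValueError("classify_bias requires a q_value (run bh_fdr first)")
    if not call.rejected or not call.tested:
        return replace(call, bias="none")
    if call.log2_fold > 0:
        return replace(call, bias="tissue_1")
    if call.log2_fold < 0:
        return replace(call, bias="tissue_2")
    logger.warning("gene %s significant in %s with log2_fold = 0; no bias assigned",
                   call.gene_id, call.contrast)
    return replace(call, bias="none")


def apply_fdr(calls: Sequence[DECall], config: Config = DEFAULT_CONFIG
              ) -> list[DECall]:
    """BH-correct each contrast separately and classify bias for every call."""
    out: list[DECall] = []
    for contrast in CONTRASTS:
        subset = [c for c in calls if c.contrast == contrast and c.tested]
        if not subset:
            continue
        qmap = bh_fdr({c.gene_id: c.p_value for c in subset}, config.fdr_alpha)
        for c in subset:
            q, rej = qmap[c.gene_id]
            out.append(classify_bias(replace(c, q_value=q, rejected=rej),
                                     config.fdr_alpha))
    untested = [c for c in calls if not c.tested]
    out.extend(replace(c, bias="none") for c in untested)
    return out


def significant_tested(calls: Sequence[DECall]) -> dict[str, tuple[int, int]]:
    """Per contrast: (number significant, number tested)."""
    out = {}
    for contrast in CONTRASTS:
        subset = [c for c in calls if c.contrast == contrast and c.tested]
        out[contrast] = (sum(c.rejected for c in subset), len(subset))
    return out


def _unique_first_order(orthologs: Iterable[OrthologPair]) -> dict[str, str]:
    """gene_a -> gene_b over first-order pairs, dropping ambiguous genes.

    A gene participating in more than one first-order pair (on either side)
    is excluded: concordance compares one gene with one ortholog.
    """
    first = [p for p in orthologs if p.first_order]
    count_a: dict[str, int] = {}
    count_b: dict[str, int] = {}
    for p in first:
        count_a[p.gene_a] = count_a.get(p.gene_a, 0) + 1
        count_b[p.gene_b] = count_b.get(p.gene_b, 0) + 1
    mapping = {}
    dropped = 0
    for p in first:
        if count_a[p.gene_a] == 1 and count_b[p.gene_b] == 1:
            mapping[p.gene_a] = p.gene_b
        else:
            dropped += 1
    if dropped:
        logger.info("concordance: dropped %d ambiguous many-to-many ortholog pairs",
                    dropped)
    return mapping


def concordance(calls_a: Sequence[DECall], calls_b: Sequence[DECall],
                orthologs: Sequence[OrthologPair], contrast: str
                ) -> ConcordanceSummary:
    """Fraction of species-A tissue-biased genes whose unique first-order
    ortholog shows the same bias direction in species B."""
    mapping = _unique_first_order(orthologs)
    bias_a = {c.gene_id: c.bias for c in calls_a if c.contrast == contrast}
    bias_b = {c.gene_id: c.bias for c in calls_b if c.contrast == contrast}
    denom = 0
    num = 0
    for gene_a, bias in bias_a.items():
        if bias == "none" or gene_a not in mapping:
            continue
        denom += 1
        if bias_b.get(mapping[gene_a]) == bias:
            num += 1
    fraction = num / denom if denom else 0.0
    return ConcordanceSummary(contrast, denom, num, fraction)


def de_any_contrast(calls: Sequence[DECall], gene_ids: Iterable[str]
                    ) -> dict[str, bool]:
    """gene -> True iff rejected in at least one of the four contrasts."""
    rejected = {c.gene_id for c in calls if c.rejected}
    return {g: g in rejected for g in gene_ids}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_de_tsv(path: str | Path) -> list[DECall]:
    """Read a TSV with columns gene_id, contrast, p_value, log2_fold."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "contrast", "p_value", "log2_fold"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"DE TSV missing columns {sorted(missing)}")
    return [DECall(str(r["gene_id"]), str(r["contrast"]),
                   float(r["p_value"]), float(r["log2_fold"]))
            for _, r in df.iterrows()]


def write_de_tsv(calls: Sequence[DECall], path: str | Path) -> None:
    rows = [{"gene_id": c.gene_id, "contrast": c.contrast, "p_value": c.p_value,
             "log2_fold": c.log2_fold, "q_value": c.q_value, "bias": c.bias,
             "rejected": c.rejected} for c in calls]
    pd.DataFrame(rows, columns=["gene_id", "contrast", "p_value", "log2_fold",
                                "q_value", "bias", "rejected"]).to_csv(
        path, sep="\t", index=False)
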