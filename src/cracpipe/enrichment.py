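"""CRAC-vs-RNA-seq enrichment: TPM normalization and target calling.

Targets are transcripts whose CRAC read density, in transcripts per million
(TPM), exceeds their RNA-seq TPM by a fold threshold (default 4) while the
RNA-seq abundance clears a floor (default 20 TPM) that guards against
ratios driven by near-zero denominators.  An optional exact binomial test
with Benjamini–Hochberg correction is provided as a per-gene diagnostic;
it is deliberately simpler than shrinkage-based differential methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_FOLD = 4.0
DEFAULT_MIN_RNA_TPM = 20.0


@dataclass(frozen=True)
class EnrichmentRecord:
    gene_id: str
    crac_tpm: float
    rnaseq_tpm: float
    fold: float  # NaN when rnaseq_tpm == 0
    is_target: bool


def compute_tpm(counts: Mapping[str, int], lengths: Mapping[str, int]
                ) -> dict[str, float]:
    """Transcripts per million: length-normalized rates scaled to sum 1e6.

    rate_g = count_g / (length_g / 1000); tpm_g = 1e6 * rate_g / sum(rates).
    All-zero counts give all-zero TPM.
    """
    missing = set(counts) - set(lengths)
    if missing:
        raise KeyError(f"genes without lengths: {sorted(missing)[:5]}")
    genes = sorted(counts)
    rates = np.array(
        [counts[g] / (lengths[g] / 1000.0) for g in genes], dtype=float
    )
    total = rates.sum()
    if total == 0:
        return {g: 0.0 for g in genes}
    tpm = 1e6 * rates / total
    return dict(zip(genes, tpm))


def mean_tpm(replicates: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Mean TPM over replicate samples (genes = union, absent -> 0)."""
    genes = sorted(set().union(*[set(r) for r in replicates]))
    return {
        g: float(np.mean([r.get(g, 0.0) for r in replicates])) for g in genes
    }


def call_targets(
    crac_tpm: Mapping[str, float],
    rnaseq_tpm: Mapping[str, float],
    min_fold: float = DEFAULT_MIN_FOLD,
    min_rna_tpm: float = DEFAULT_MIN_RNA_TPM,
) -> list[EnrichmentRecord]:
    """Call bound targets: fold = crac/rnaseq TPM ratio; a gene is a target
    iff fold >= min_fold and rnaseq_tpm >= min_rna_tpm."""
    genes = sorted(set(crac_tpm) | set(rnaseq_tpm))
    out = []
    for g in genes:
        c = float(crac_tpm.get(g, 0.0))
        r = float(rnaseq_tpm.get(g, 0.0))
        fold = c / r if r > 0 else float("nan")
        is_target = r >= min_rna_tpm and r > 0 and fold >= min_fold
        out.append(EnrichmentRecord(g, c, r, fold, is_target))
    return out


def binomial_enrichment_test(
    crac_count: int, crac_total: int, rnaseq_count: int, rnaseq_total: int
) -> float:
    """Exact binomial upper-tail p-value for CRAC over-representation.

    Tests crac_count successes in crac_total trials against the RNA-seq
    proportion p0 = rnaseq_count / rnaseq_total.  With p0 == 0 and a
    positive observed count, the smallest positive float is returned.
    """
    if crac_total <= 0 or rnaseq_total <= 0:
        raise ValueError("totals must be positive")
    p0 = rnaseq_count / rnaseq_total
    if p0 == 0:
        return 1.0 if crac_count == 0 else float(np.nextafter(0, 1))
    return float(
        stats.binomtest(crac_count, crac_total, p0, alternative="greater").pvalue
    )


def enrichment_table(
    records: Sequence[EnrichmentRecord],
    crac_counts: Mapping[str, int] | None = None,
    rnaseq_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Assemble the enrichment report; when raw counts are supplied, add the
    binomial diagnostic p-values with Benjamini–Hochberg adjustment."""
    df = pd.DataFrame(
        [
            {"gene_id": r.gene_id, "crac_tpm": r.crac_tpm,
             "rnaseq_tpm": r.rnaseq_tpm, "fold": r.fold,
             "is_target": r.is_target}
            for r in records
        ]
    )
    if crac_counts is not None and rnaseq_counts is not None:
        ct, rt = sum(crac_counts.values()), sum(rnaseq_counts.values())
        pvals = [
            binomial_enrichment_test(
                crac_counts.get(g, 0), ct, rnaseq_counts.get(g, 0), rt
            )
            for g in df["gene_id"]
        ]
        df["binom_p"] = pvals
        df["binom_p_bh"] = multipletests(pvals, method="fdr_bh")[1]
    return df
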