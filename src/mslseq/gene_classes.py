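"""Gene classification from binding and expression, CDS thirds, and the
group-comparison statistics.

Genes whose binding value (log2) exceeds 1.0 for all three MSL proteins are
"strong"; below 0.5 for all three, "weak"; in between, intermediate and
excluded from model sets.  Expression is the median over replicates; genes
in [6, 10] are expressed, below 6 unexpressed, above 10 expressed but
excluded (expression effects are only quantifiable inside the window).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats as sps

from . import kmer
from ._dna import encode, window_codes, code_to_word
from .errors import InputError, ParameterError, SchemaError

STRONG_THRESHOLD = 1.0
WEAK_THRESHOLD = 0.5
EXPRESSION_WINDOW = (6.0, 10.0)


def classify_genes(
    binding: pd.DataFrame,
    expression: pd.DataFrame,
    proteins: Sequence[str] | None = None,
    strong_threshold: float = STRONG_THRESHOLD,
    weak_threshold: float = WEAK_THRESHOLD,
    expression_window: tuple[float, float] = EXPRESSION_WINDOW,
) -> pd.DataFrame:
    """Assign mutually exclusive gene classes.

    ``binding`` holds one column per protein (gene binding values, log2);
    ``expression`` one column per replicate.  Returns a table with the
    median expression, per-protein binding, average MSL enrichment and the
    class label.
    """
    proteins = list(proteins or binding.columns)
    missing = [p for p in proteins if p not in binding.columns]
    if missing:
        raise SchemaError(f"binding table lacks protein column(s) {missing}")
    if expression.shape[1] < 1:
        raise SchemaError("expression table needs at least one replicate column")

    genes = binding.index.intersection(expression.index)
    b = binding.loc[genes, proteins]
    expr = expression.loc[genes].median(axis=1)
    lo, hi = expression_window

    all_strong = (b > strong_threshold).all(axis=1)
    all_weak = (b < weak_threshold).all(axis=1)
    cls = pd.Series("intermediate", index=genes, dtype=object)
    cls[all_strong] = "strong_expressed"
    cls[all_weak] = "weak_expressed"
    cls[expr > hi] = "excluded_high_expression"
    cls[expr < lo] = "unexpressed"

    out = b.copy()
    out["expression"] = expr
    out["avg_msl"] = b.mean(axis=1)
    out["gene_class"] = cls
    return out


def split_cds_thirds(cds: str, min_length: int = 18) -> tuple[str, str, str] | None:
    """Split a coding sequence into three near-equal parts (5', mid, 3').

    Lengths differ by at most one; remainder bases go to the 5'-most parts.
    CDS shorter than ``min_length`` are excluded with a warning (returns
    None).
    """
    n = len(cds)
    if n < min_length:
        warnings.warn(
            f"CDS of length {n} < {min_length} excluded from thirds analysis",
            stacklevel=2,
        )
        return None
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    i1 = sizes[0]
    i2 = sizes[0] + sizes[1]
    return cds[:i1], cds[i1:i2], cds[i2:]


def thirds_bias_test(
    model,
    cds_by_gene: Mapping[str, str],
    k_min: int = 2,
    k_max: int = 6,
    layout: str = "canonical",
):
    """Score each CDS third with an OPLS-DA model and test the 3' bias.

    Returns ``(scores, result)``: per-gene prediction scores of the 5',
    middle and 3' thirds, and a paired t-test of 3' vs 5' scores (positive
    statistic = better predicted 3' ends).
    """
    from .multivariate import predict_scores

    parts: dict[str, dict[str, str]] = {"five_prime": {}, "middle": {}, "three_prime": {}}
    for gid, cds in cds_by_gene.items():
        split = split_cds_thirds(cds)
        if split is None:
            continue
        parts["five_prime"][gid], parts["middle"][gid], parts["three_prime"][gid] = split
    if not parts["five_prime"]:
        raise InputError("no CDS long enough for the thirds analysis")
    scores = {}
    for name, seqs in parts.items():
        m = kmer.build_word_matrix(seqs, k_min, k_max, layout)
        scores[name] = predict_scores(model, m)
    df = pd.DataFrame(scores)
    if len(df) < 2:
        result = dict(statistic=float("nan"), p_value=float("nan"),
                      n=len(df), insufficient_n=True)
        return df, result
    stat, p = sps.ttest_rel(df["three_prime"], df["five_prime"])
    return df, dict(statistic=float(stat), p_value=float(p), n=len(df),
                    insufficient_n=False)


def strand_frame_variants(
    cds: str, mode: str, k_min: int = 2, k_max: int = 6
) -> pd.Series:
    """Word frequencies under alternative counting conventions.

    ``both_strands``: canonical reverse-complement-merged counting;
    ``transcribed_only``: no merging, coding strand only;
    ``in_frame_only``: windows advancing 3 nt from frame 0, no merging
    (length is truncated to a codon boundary with a warning if needed).
    """
    if mode == "both_strands":
        return kmer.word_frequencies(cds, k_min, k_max, layout="canonical")
    if mode not in ("transcribed_only", "in_frame_only"):
        raise ParameterError(f"unknown mode {mode!r}")
    seq = cds
    if mode == "in_frame_only" and len(seq) % 3 != 0:
        warnings.warn("CDS length not divisible by 3; truncating to codon boundary",
                      stacklevel=2)
        seq = seq[: len(seq) - len(seq) % 3]
    if len(seq) < k_max:
        raise InputError("sequence shorter than k_max")
    codes = encode(seq)
    L = len(seq)
    out = []
    labels = []
    for k in range(k_min, k_max + 1):
        vals, valid = window_codes(codes, k)
        if mode == "in_frame_only":
            keep = np.zeros(vals.size, dtype=bool)
            keep[::3] = True
            valid = valid & keep
        counts = np.bincount(vals[valid], minlength=4**k)
        out.append(counts / L)
        labels.extend(code_to_word(c, k) for c in range(4**k))
    return pd.Series(np.concatenate(out), index=labels, dtype=float)


_STANDARD = CodonTable.unambiguous_dna_by_id[1]


def _degenerate_codons() -> dict[str, str]:
    """codon -> amino acid for the 59 codons in degenerate families."""
    fam: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    return {c: aa for aa, codons in fam.items() if len(codons) > 1 for c in codons}


def _codon_counts(cds_list: Sequence[str]) -> pd.Series:
    counts: dict[str, int] = {}
    for cds in cds_list:
        cds = cds[: len(cds) - len(cds) % 3]
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return pd.Series(counts, dtype=float)


def rscu(cds_list: Sequence[str]) -> pd.Series:
    """Relative synonymous codon usage over the degenerate codons.

    RSCU of a codon is its count divided by the mean count of its
    synonymous family (1.0 = unbiased usage).
    """
    if not cds_list:
        raise InputError("empty CDS set")
    deg = _degenerate_codons()
    counts = _codon_counts(cds_list).reindex(sorted(deg), fill_value=0.0)
    fam_mean = counts.groupby(pd.Series(deg)).transform("mean")
    with np.errstate(invalid="ignore"):
        values = np.where(fam_mean > 0, counts / fam_mean, np.nan)
    return pd.Series(values, index=counts.index, name="rscu")


def relative_adaptiveness(cds_list: Sequence[str]) -> pd.Series:
    """Codon relative adaptiveness w = RSCU / max RSCU of the synonymous
    family (the CAI weight); 1.0 marks each family's preferred codon.

    Unlike raw RSCU, whose differences sum to zero across codons by
    construction, w differences carry a usable mean signal.
    """
    r = rscu(cds_list)
    deg = pd.Series(_degenerate_codons())
    fam_max = r.groupby(deg).transform("max")
    with np.errstate(invalid="ignore"):
        return (r / fam_max).rename("w")


def codon_usage_compare(set_a: Sequence[str], set_b: Sequence[str]) -> dict:
    """Compare synonymous codon usage between two CDS sets.

    Reports a paired t-test across the 59 degenerate codons on relative
    adaptiveness (w), plus a within-family G-test on pooled codon counts —
    the count-based test has far more power for shifts confined to one
    amino-acid family.
    """
    ra, rb = rscu(set_a), rscu(set_b)
    wa = relative_adaptiveness(set_a)
    wb = relative_adaptiveness(set_b)
    ok = wa.notna() & wb.notna()
    diffs = (wa[ok] - wb[ok]).to_numpy()
    degenerate = bool(np.allclose(diffs, 0.0))
    if degenerate:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_rel(wa[ok], wb[ok])

    # within-family G-test on pooled counts
    deg = _degenerate_codons()
    counts_a = _codon_counts(set_a).reindex(sorted(deg), fill_value=0.0)
    counts_b = _codon_counts(set_b).reindex(sorted(deg), fill_value=0.0)
    fam = pd.Series(deg)
    g_stat, g_df = 0.0, 0
    for _, codons in fam.groupby(fam):
        table = np.vstack([counts_a[codons.index], counts_b[codons.index]])
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            continue
        res = sps.chi2_contingency(table, lambda_="log-likelihood")
        g_stat += float(res.statistic)
        g_df += int(res.dof)
    g_p = float(sps.chi2.sf(g_stat, g_df)) if g_df else 1.0

    return dict(statistic=float(stat), p_value=float(p), n_codons=int(ok.sum()),
                degenerate=degenerate, g_statistic=g_stat, g_p_value=g_p,
                rscu_a=ra, rscu_b=rb)


def compare_groups(
    values_a,
    values_b,
    test: str = "mann_whitney",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Standard two-group comparisons: Mann-Whitney U (exact for n <= 20),
    paired t, or Spearman correlation.  Returns (statistic, p)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if test == "mann_whitney":
        method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    elif test == "paired_t":
        if a.size != b.size:
            raise InputError("paired test needs equal-length samples")
        res = sps.ttest_rel(a, b, alternative=alternative)
    elif test == "spearman":
        if a.size != b.size:
            raise InputError("correlation needs equal-length samples")
        res = sps.spearmanr(a, b, alternative=alternative)
    else:
        raise ParameterError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
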