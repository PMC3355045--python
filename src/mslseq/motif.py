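"""Iterative word-to-PWM motif construction.

Top-loaded discriminative sequence words are aligned into position weight
matrices: the PWM accumulates each aligned word's loading in the matching
base cells and every column is renormalized to sum to one.  A PWM is scored
in a sequence as the product of matching column values at an offset (both
strands, max per position) and the sum of the best ``best_scores_per_seq``
positions.  Each candidate update is gated by logistic regression: the
extension is accepted only if it lowers the deviance of class ~ score and
the updated score remains significant against the intercept-only model.
When a motif can no longer be improved, its above-cutoff occurrences are
masked with N in all sequences and the next motif is seeded from the top
unconsumed word.  Cutoffs are calibrated to a target false-positive rate on
the weakly-bound (negative) promoter set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from ._dna import BASES, encode, revcomp
from .errors import InputError, ParameterError, StateError


@dataclass
class AlignerParams:
    top_n_words: int = 1000
    best_scores_per_seq: int = 1
    min_overlap: int | None = None  # default: ceil(word length / 2)
    max_motifs: int = 5
    improvement_alpha: float = 0.05
    #: gate (logistic-regression) evaluations per extension round, walking
    #: candidates in order of alignment compatibility
    max_gate_trials: int = 25
    #: stop seeding once the top unconsumed loading falls below this
    #: fraction of the maximum loading
    min_loading_fraction: float = 0.10
    #: rejected seed motifs tolerated before giving up; the default stops
    #: at the first seed that fails the gate (each retry is another
    #: 5%-level test, so retries inflate the junk-motif rate under the null)
    max_seed_attempts: int = 1
    target_fpr: float = 0.05

    def __post_init__(self):
        if self.top_n_words < 1:
            raise ParameterError("top_n_words must be >= 1")
        if self.best_scores_per_seq < 1:
            raise ParameterError("best_scores_per_seq must be >= 1")


@dataclass
class PwmMotif:
    """A position weight matrix built from loaded words.

    ``weights`` carries the accumulated loadings (L x 4); ``columns``
    renormalizes each row to sum to one.
    """

    weights: np.ndarray
    source_words: list[tuple[str, float]] = field(default_factory=list)
    cutoff: float | None = None
    fit_stat: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise InputError("PWM weights must be an L x 4 matrix")
        if (self.weights.sum(axis=1) <= 0).any():
            raise InputError("every PWM column needs positive total weight")

    @classmethod
    def from_word(cls, word: str, loading: float) -> "PwmMotif":
        if loading <= 0:
            raise ParameterError("word loading must be positive")
        w = np.zeros((len(word), 4))
        for i, b in enumerate(word):
            w[i, BASES.index(b)] = loading
        return cls(weights=w, source_words=[(word, loading)])

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def columns(self) -> np.ndarray:
        return self.weights / self.weights.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.columns.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        p = np.clip(self.columns, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


def _cols5(columns: np.ndarray) -> np.ndarray:
    """Columns extended with a zero N-column; N contributes score 0."""
    return np.hstack([columns, np.zeros((columns.shape[0], 1))])


def _rc_columns(columns: np.ndarray) -> np.ndarray:
    return columns[::-1, ::-1]


def position_scores(pwm: PwmMotif, sequence: str) -> np.ndarray:
    """Per-offset PWM score, max over strands."""
    L = pwm.length
    if len(sequence) < L:
        raise InputError(f"sequence shorter than motif length {L}")
    codes = encode(sequence)
    n = codes.size - L + 1
    fwd = _cols5(pwm.columns)
    rev = _cols5(_rc_columns(pwm.columns))
    sf = np.ones(n)
    sr = np.ones(n)
    for i in range(L):
        window = codes[i : i + n]
        sf *= fwd[i, window]
        sr *= rev[i, window]
    return np.maximum(sf, sr)


def score_pwm(pwm: PwmMotif, sequence: str, top_n: int = 1) -> float:
    """Sum of the ``top_n`` best per-position scores in ``sequence``."""
    ps = position_scores(pwm, sequence)
    if top_n >= ps.size:
        return float(ps.sum())
    return float(np.sort(ps)[::-1][:top_n].sum())


def score_sequences(pwm: PwmMotif, sequences, top_n: int = 1) -> np.ndarray:
    return np.array([score_pwm(pwm, s, top_n) for s in sequences])


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

@dataclass
class Candidate:
    weights: np.ndarray
    word: str
    loading: float
    orientation: str  # 'fwd' | 'rev'
    offsets: tuple[int, ...]
    compatibility: float


def _single_candidates(pwm: PwmMotif, word: str, loading: float, min_overlap: int):
    L = pwm.length
    cols = pwm.columns
    wlen = len(word)
    out = []
    for orientation, w in (("fwd", word), ("rev", revcomp(word))):
        if orientation == "rev" and w == word:
            continue  # palindromic: identical alignment
        bases = [BASES.index(b) for b in w]
        for offset in range(-(wlen - min_overlap), L - min_overlap + 1):
            lo = max(0, offset)
            hi = min(L, offset + wlen)
            if hi - lo < min_overlap:
                continue
            compat = float(
                sum(cols[i, bases[i - offset]] for i in range(lo, hi))
            )
            new_len = max(L, offset + wlen) - min(0, offset)
            shift = -min(0, offset)
            weights = np.zeros((new_len, 4))
            weights[shift : shift + L] += pwm.weights
            for i, b in enumerate(bases):
                weights[offset + shift + i, b] += loading
            out.append(
                Candidate(weights, word, loading, orientation, (offset,), compat)
            )
    return out


def align_word(
    pwm: PwmMotif, word: str, loading: float, params: AlignerParams | None = None
) -> list[Candidate]:
    """Candidate extensions of ``pwm`` by ``word``.

    Both orientations and every offset with sufficient overlap are tested
    (overhangs extend the PWM); additionally the best two distinct offsets
    are combined into one simultaneous-alignment candidate.  Candidates are
    ranked by alignment compatibility: the dot product of the word's one-hot
    matrix with the current (pre-update) PWM columns over the overlap.
    """
    if loading <= 0:
        raise ParameterError("word loading must be positive")
    if not 2 <= len(word) <= 6:
        raise ParameterError("words must be 2-6 bp")
    params = params or AlignerParams()
    min_overlap = params.min_overlap or math.ceil(len(word) / 2)
    cands = _single_candidates(pwm, word, loading, min_overlap)
    cands.sort(key=lambda c: -c.compatibility)
    # combine the two best distinct offsets into a simultaneous alignment
    if len(cands) >= 2:
        best = cands[0]
        other = next(
            (c for c in cands[1:] if c.offsets != best.offsets), None
        )
        if other is not None:
            L = pwm.length
            off_a, off_b = best.offsets[0], other.offsets[0]
            lo = min(0, off_a, off_b)
            new_len = max(L, off_a + len(word), off_b + len(word)) - lo
            weights = np.zeros((new_len, 4))
            weights[-lo : -lo + L] += pwm.weights
            for cand in (best, other):
                w = cand.word if cand.orientation == "fwd" else revcomp(cand.word)
                for i, b in enumerate(w):
                    weights[cand.offsets[0] - lo + i, BASES.index(b)] += loading
            cands.append(
                Candidate(
                    weights,
                    word,
                    loading,
                    f"{best.orientation}+{other.orientation}",
                    (off_a, off_b),
                    best.compatibility + other.compatibility,
                )
            )
            cands.sort(key=lambda c: -c.compatibility)
    return cands


# --------------------------------------------------------------------------
# logistic gate
# --------------------------------------------------------------------------

def _logit_fit(scores: np.ndarray, y: np.ndarray):
    """(deviance, p-value of the LR test vs intercept-only), or None when
    the scores are degenerate."""
    if np.ptp(scores) == 0:
        return None
    sd = scores.std()
    x = (scores - scores.mean()) / sd
    X = sm.add_constant(x)
    n1 = int(y.sum())
    n0 = y.size - n1
    p1 = n1 / y.size
    llnull = n1 * math.log(p1) + n0 * math.log(1 - p1)
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            llf = float(res.llf)
        if not np.isfinite(llf):
            raise ValueError
    except Exception:
        # (near-)perfect separation: the model fits the classes exactly
        llf = -1e-9
    llf = min(llf, 0.0)
    deviance = -2.0 * llf
    lr = max(0.0, 2.0 * (llf - llnull))
    pval = float(chi2.sf(lr, df=1))
    return deviance, pval


def accept_extension(
    old_pwm: PwmMotif,
    new_pwm: PwmMotif,
    pos_seqs,
    neg_seqs,
    params: AlignerParams | None = None,
) -> tuple[bool, float | None]:
    """Logistic-regression gate for a PWM update.

    Accept iff the new score's deviance is lower than the old one's and the
    new model is significant against intercept-only at ``improvement_alpha``.
    Degenerate (constant) scores are rejected, not an error.
    """
    params = params or AlignerParams()
    if not len(pos_seqs) or not len(neg_seqs):
        raise InputError("both sequence sets must be non-empty")
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))])
    seqs = list(pos_seqs) + list(neg_seqs)
    k = params.best_scores_per_seq
    new_fit = _logit_fit(score_sequences(new_pwm, seqs, k), y)
    if new_fit is None:
        return False, None
    old_fit = _logit_fit(score_sequences(old_pwm, seqs, k), y)
    dev_new, p_new = new_fit
    # degenerate old scores carry no information: compare against the null
    dev_old = old_fit[0] if old_fit is not None else _null_deviance(y)
    accepted = (dev_new < dev_old - 1e-9) and (p_new < params.improvement_alpha)
    return accepted, dev_new if accepted else None


def _null_deviance(y: np.ndarray) -> float:
    n1 = int(y.sum())
    n0 = y.size - n1
    p1 = n1 / y.size
    return -2.0 * (n1 * math.log(p1) + n0 * math.log(1 - p1))


def _seed_significant(pwm: PwmMotif, pos_seqs, neg_seqs, params) -> bool:
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))])
    fit = _logit_fit(
        score_sequences(pwm, list(pos_seqs) + list(neg_seqs),
                        params.best_scores_per_seq),
        y,
    )
    return fit is not None and fit[1] < params.improvement_alpha


def mask_motif(pwm: PwmMotif, sequences: list[str], n_best: int = 1) -> list[str]:
    """Replace each sequence's best above-cutoff occurrences with N."""
    if pwm.cutoff is None:
        raise StateError("motif cutoff not calibrated")
    L = pwm.length
    out = []
    for seq in sequences:
        if len(seq) < L:
            out.append(seq)
            continue
        ps = position_scores(pwm, seq)
        order = np.argsort(ps)[::-1][:n_best]
        chars = list(seq)
        for o in order:
            if ps[o] >= pwm.cutoff:
                chars[o : o + L] = "N" * L
        out.append("".join(chars))
    return out


def calibrate_cutoff(pwm: PwmMotif, neg_seqs, target_fpr: float = 0.05) -> float:
    """Smallest observed best-score such that the fraction of negative
    sequences at/above it is <= target_fpr."""
    if not len(neg_seqs):
        raise InputError("negative set is empty")
    best = score_sequences(pwm, neg_seqs, top_n=1)
    n = best.size
    for v in np.unique(best):  # ascending
        if (best >= v).sum() / n <= target_fpr:
            return float(v)
    return float(np.nextafter(best.max(), np.inf))


def motif_presence_fraction(
    pwm: PwmMotif, sequences, window: int | None = None
) -> float:
    """Fraction of sequences whose best score within ``window`` bp of the
    TSS end reaches the calibrated cutoff.

    Sequences are promoter-oriented (TSS at the right end); ``window``
    limits the scan to the last ``window`` bases.  Returns NaN for an empty
    set.
    """
    if pwm.cutoff is None:
        raise StateError("motif cutoff not calibrated")
    seqs = list(sequences)
    if not seqs:
        return float("nan")
    hits = 0
    for seq in seqs:
        if window is not None:
            seq = seq[-window:]
        if len(seq) < pwm.length:
            continue
        if score_pwm(pwm, seq, top_n=1) >= pwm.cutoff:
            hits += 1
    return hits / len(seqs)


# --------------------------------------------------------------------------
# the iterative builder
# --------------------------------------------------------------------------

def build_motifs(
    words: list[tuple[str, float]],
    pos_seqs,
    neg_seqs,
    params: AlignerParams | None = None,
) -> list[PwmMotif]:
    """Build motifs from a loading-sorted word list.

    Seeds a PWM from the top unconsumed word; a seed only counts as an
    accepted model if its score is itself significant in the logistic gate
    (insignificant seeds are consumed and skipped, up to a bounded number
    of attempts).  Accepted seeds are then repeatedly extended: every
    unconsumed word is aligned (candidates ranked by compatibility) and the
    best gate-approved extension applied; consumed words are never reused.
    On stagnation the motif's above-cutoff occurrences are masked with N in
    all sequences and the next PWM is seeded from the remaining list.
    Deterministic.
    """
    params = params or AlignerParams()
    if not words:
        raise InputError("empty word list")
    words = sorted(
        [(w, float(l)) for w, l in words if l > 0], key=lambda wl: -wl[1]
    )[: params.top_n_words]
    if not words:
        raise InputError("no words with positive loading")
    pos = list(pos_seqs)
    neg = list(neg_seqs)
    if not pos or not neg:
        raise InputError("both sequence sets must be non-empty")

    max_loading = words[0][1]
    consumed: set[str] = set()
    motifs: list[PwmMotif] = []
    failed_seeds = 0

    def unconsumed():
        return [(w, l) for w, l in words if w not in consumed]

    while len(motifs) < params.max_motifs:
        remaining = unconsumed()
        if not remaining or remaining[0][1] < params.min_loading_fraction * max_loading:
            break
        seed_word, seed_loading = remaining[0]
        consumed.add(seed_word)
        pwm = PwmMotif.from_word(seed_word, seed_loading)
        # a single-word input list is returned as its one-hot PWM; otherwise
        # the seed must itself pass the significance gate
        if len(words) > 1 and not _seed_significant(pwm, pos, neg, params):
            failed_seeds += 1
            if failed_seeds >= params.max_seed_attempts:
                break
            continue
        failed_seeds = 0

        while True:
            candidates: list[Candidate] = []
            for w, l in unconsumed():
                cands = align_word(pwm, w, l, params)
                if cands:
                    candidates.append(cands[0])  # best single/double for the word
                    for c in cands[1:]:
                        if len(c.offsets) == 2:
                            candidates.append(c)
                            break
            candidates.sort(key=lambda c: -c.compatibility)
            accepted_cand = None
            for cand in candidates[: params.max_gate_trials]:
                new_pwm = PwmMotif(
                    weights=cand.weights,
                    source_words=pwm.source_words + [(cand.word, cand.loading)],
                )
                ok, stat = accept_extension(pwm, new_pwm, pos, neg, params)
                if ok:
                    new_pwm.fit_stat = stat
                    accepted_cand = (cand, new_pwm)
                    break
            if accepted_cand is None:
                break
            cand, pwm = accepted_cand
            consumed.add(cand.word)

        pwm.cutoff = calibrate_cutoff(pwm, neg, params.target_fpr)
        motifs.append(pwm)
        pos = mask_motif(pwm, pos, params.best_scores_per_seq)
        neg = mask_motif(pwm, neg, params.best_scores_per_seq)
    return motifs


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def write_meme(motifs: list[PwmMotif], path, names: list[str] | None = None) -> None:
    """Write motifs in MEME minimal format."""
    names = names or [f"motif_{i + 1}" for i in range(len(motifs))]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for name, m in zip(names, motifs):
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {max(1, len(m.source_words))} E= 0\n"
            )
            for row in m.columns:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_pwm_tsv(pwm: PwmMotif, path) -> None:
    import pandas as pd

    df = pd.DataFrame(pwm.columns, columns=list(BASES))
    df.index.name = "position"
    df.to_csv(path, sep="\t")
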