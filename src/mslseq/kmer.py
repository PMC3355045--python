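"""Sequence-word (k-mer) profiling: counting, frequency matrices,
AT normalization, and scaling.

Words of length 2-6 are counted in sliding windows of step one; a word and
its reverse complement are treated as one ("canonical" counting, the
canonical key being the lexicographically smaller of the pair).  Frequencies
divide the merged count by the *full* sequence length L, not by the number
of windows.

Two column layouts are supported:

``as_published``
    one column per literal word (16+64+256+1024+4096 = 5456 columns for
    k = 2..6); a word column and its reverse-complement column carry
    identical values.
``canonical``
    one column per reverse-complement equivalence class (2770 columns for
    k = 2..6), the efficient layout for modeling.

AT normalization divides each word frequency by its expected frequency
under the observation's own mononucleotide composition, assuming i.i.d.
bases; for a non-palindromic canonical class the expectation is the sum
over both members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import _dna
from .errors import InputError, ParameterError, StateError

K_MIN_ALLOWED = 2
K_MAX_ALLOWED = 6

#: Separator inserted between pooled member sequences; counted as N so no
#: spurious junction words arise.
POOL_SEPARATOR = "N"


@lru_cache(maxsize=None)
def _rc_code_table(k: int) -> np.ndarray:
    """code -> code of reverse complement, for all 4**k words."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


@lru_cache(maxsize=None)
def _canonical_code_table(k: int) -> np.ndarray:
    """code -> canonical (min of code and rc-code)."""
    codes = np.arange(4**k, dtype=np.int64)
    return np.minimum(codes, _rc_code_table(k))


@lru_cache(maxsize=None)
def canonical_words(k: int) -> tuple[str, ...]:
    """Canonical words of length k in lexicographic order."""
    canon = np.unique(_canonical_code_table(k))
    return tuple(_dna.code_to_word(int(c), k) for c in canon)


@lru_cache(maxsize=None)
def all_words(k: int) -> tuple[str, ...]:
    return tuple(_dna.code_to_word(c, k) for c in range(4**k))


def word_labels(k_min: int = 2, k_max: int = 6, layout: str = "as_published") -> list[str]:
    """Column labels in fixed order: k ascending, then lexicographic."""
    _check_k(k_min, k_max)
    out: list[str] = []
    for k in range(k_min, k_max + 1):
        out.extend(canonical_words(k) if layout == "canonical" else all_words(k))
    return out


def _check_k(k_min: int, k_max: int) -> None:
    if not (K_MIN_ALLOWED <= k_min <= k_max <= K_MAX_ALLOWED):
        raise ParameterError(
            f"word lengths must satisfy {K_MIN_ALLOWED} <= k_min <= k_max <= "
            f"{K_MAX_ALLOWED}, got [{k_min}, {k_max}]"
        )


def _canonical_counts_array(codes: np.ndarray, k: int) -> np.ndarray:
    """Merged counts indexed by canonical code (length 4**k, zeros on
    non-canonical slots)."""
    vals, valid = _dna.window_codes(codes, k)
    if vals.size == 0:
        return np.zeros(4**k, dtype=np.int64)
    canon = _canonical_code_table(k)[vals[valid]]
    return np.bincount(canon, minlength=4**k)


def count_words(sequence: str, k: int) -> dict[str, int]:
    """Count canonical k-words in ``sequence`` (sliding windows, step 1).

    Forward and reverse complements are merged into the lexicographically
    smaller word; windows containing N are skipped.
    """
    _check_k(k, k)
    counts = _canonical_counts_array(_dna.encode(sequence), k)
    nz = np.nonzero(counts)[0]
    return {_dna.code_to_word(int(c), k): int(counts[c]) for c in nz}


def word_frequencies(
    sequence: str,
    k_min: int = 2,
    k_max: int = 6,
    layout: str = "as_published",
) -> pd.Series:
    """Frequency vector over k_min..k_max words: merged count / L.

    L is the full sequence length (not the window count), following the
    count-then-divide-by-length convention.
    """
    _check_k(k_min, k_max)
    if len(sequence) == 0:
        raise InputError("cannot profile an empty sequence")
    if len(sequence) < k_max:
        raise InputError(
            f"sequence length {len(sequence)} shorter than k_max={k_max}"
        )
    codes = _dna.encode(sequence)
    L = len(sequence)
    parts: list[np.ndarray] = []
    for k in range(k_min, k_max + 1):
        counts = _canonical_counts_array(codes, k)
        if layout == "canonical":
            canon = np.unique(_canonical_code_table(k))
            parts.append(counts[canon] / L)
        else:
            # mirror each canonical value into both complement columns
            parts.append(counts[_canonical_code_table(k)] / L)
    return pd.Series(
        np.concatenate(parts), index=word_labels(k_min, k_max, layout), dtype=float
    )


def pool_sequences(sequences: Iterable[str]) -> str:
    """Concatenate member sequences with an N separator (no junction words)."""
    return POOL_SEPARATOR.join(sequences)


@dataclass
class WordMatrix:
    """Observations × word-frequency matrix with explicit processing state.

    ``data`` rows are observations (pooled groups or single genes), columns
    are word labels.  ``base_probs`` stores each observation's own
    mononucleotide composition (needed for AT normalization), and
    ``at_content`` its A+T fraction.
    """

    data: pd.DataFrame
    k_min: int = 2
    k_max: int = 6
    layout: str = "as_published"
    norm_state: str = "raw"  # raw | at_normalized
    scale_state: str = "unscaled"  # unscaled | centered | uv_scaled
    base_probs: pd.DataFrame | None = None
    column_means: pd.Series | None = field(default=None, repr=False)
    column_sds: pd.Series | None = field(default=None, repr=False)

    @property
    def observation_ids(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def at_content(self) -> pd.Series:
        if self.base_probs is None:
            raise StateError("matrix carries no base composition")
        return self.base_probs["A"] + self.base_probs["T"]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"#mslseq WordMatrix k={self.k_min}..{self.k_max} "
                f"layout={self.layout} norm={self.norm_state} "
                f"scale={self.scale_state}\n"
            )
            self.data.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "WordMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#mslseq WordMatrix"):
                raise InputError(f"{path}: missing WordMatrix state header")
            fields = dict(tok.split("=", 1) for tok in header.split()[2:])
            data = pd.read_csv(fh, sep="\t", index_col=0)
        k_min, k_max = (int(x) for x in fields["k"].split(".."))
        return cls(
            data=data,
            k_min=k_min,
            k_max=k_max,
            layout=fields["layout"],
            norm_state=fields["norm"],
            scale_state=fields["scale"],
        )


def build_word_matrix(
    sequences: Mapping[str, str | Iterable[str]],
    k_min: int = 2,
    k_max: int = 6,
    layout: str = "as_published",
) -> WordMatrix:
    """Build a raw frequency matrix, one row per named observation.

    A value may be a single sequence or an iterable of member sequences;
    members are pooled with an N separator before counting.
    """
    if not sequences:
        raise InputError("no observations supplied")
    rows, probs = [], []
    ids = []
    for obs_id, seq in sequences.items():
        if not isinstance(seq, str):
            seq = pool_sequences(seq)
        rows.append(word_frequencies(seq, k_min, k_max, layout).to_numpy())
        probs.append(_dna.base_composition(seq))
        ids.append(obs_id)
    labels = word_labels(k_min, k_max, layout)
    data = pd.DataFrame(np.vstack(rows), index=ids, columns=labels)
    base = pd.DataFrame(np.vstack(probs), index=ids, columns=list("ACGT"))
    return WordMatrix(data=data, k_min=k_min, k_max=k_max, layout=layout, base_probs=base)


_PROB_FLOOR = 1e-6


def expected_frequency(word: str, base_probs) -> float:
    """Expected merged frequency of a word under i.i.d. bases.

    E(word) = prod_i p(word_i); for a non-palindromic word the merged
    expectation adds E(revcomp(word)); a self-complementary word is not
    doubled.  Base probabilities are floored at 1e-6.
    """
    p = np.maximum(np.asarray(base_probs, dtype=float), _PROB_FLOOR)
    if p.shape != (4,):
        raise ParameterError("base_probs must be a 4-vector (A,C,G,T)")

    def _e(w: str) -> float:
        out = 1.0
        for b in w:
            out *= p["ACGT".index(b)]
        return out

    rc = _dna.revcomp(word)
    if rc == word:
        return _e(word)
    return _e(word) + _e(rc)


def _expected_matrix(words: list[str], base_probs: pd.DataFrame) -> np.ndarray:
    """Expected merged frequency for every (observation, word) cell."""
    logp = np.log(np.maximum(base_probs[list("ACGT")].to_numpy(float), _PROB_FLOOR))
    n_fwd = np.zeros((len(words), 4))
    n_rc = np.zeros((len(words), 4))
    palin = np.zeros(len(words), dtype=bool)
    for j, w in enumerate(words):
        rc = _dna.revcomp(w)
        palin[j] = rc == w
        for b in w:
            n_fwd[j, "ACGT".index(b)] += 1
        for b in rc:
            n_rc[j, "ACGT".index(b)] += 1
    e_fwd = np.exp(logp @ n_fwd.T)
    e_rc = np.exp(logp @ n_rc.T)
    return np.where(palin[None, :], e_fwd, e_fwd + e_rc)


def at_normalize(matrix: WordMatrix) -> WordMatrix:
    """Divide each cell by its expected frequency under the observation's
    own mononucleotide composition."""
    if matrix.norm_state != "raw":
        raise StateError(f"matrix already {matrix.norm_state}")
    if matrix.scale_state != "unscaled":
        raise StateError("normalize before scaling")
    if matrix.base_probs is None:
        raise StateError("matrix carries no base composition to normalize with")
    expected = _expected_matrix(matrix.variables, matrix.base_probs)
    data = matrix.data / expected
    return replace(matrix, data=data, norm_state="at_normalized")


def scale_matrix(matrix: WordMatrix, mode: str) -> WordMatrix:
    """Center (AT-normalized data) or unit-variance scale (raw data).

    The convention is: AT-normalized matrices are center-scaled only; raw
    matrices get full UV scaling.  Column stats are retained so the same
    transform can be applied to new observations.
    """
    if matrix.scale_state != "unscaled":
        raise StateError(f"matrix already {matrix.scale_state}")
    if mode == "centered":
        if matrix.norm_state != "at_normalized":
            raise StateError("center scaling is reserved for AT-normalized data")
        means = matrix.data.mean(axis=0)
        sds = pd.Series(1.0, index=matrix.data.columns)
    elif mode == "uv_scaled":
        if matrix.norm_state != "raw":
            raise StateError("UV scaling is reserved for raw frequency data")
        means = matrix.data.mean(axis=0)
        sds = matrix.data.std(axis=0, ddof=1)
        sds = sds.where(sds > 0, 1.0)  # zero-variance columns stay at 0
    else:
        raise ParameterError(f"unknown scaling mode {mode!r}")
    data = (matrix.data - means) / sds
    return replace(
        matrix, data=data, scale_state=mode, column_means=means, column_sds=sds
    )


def apply_column_stats(
    data: pd.DataFrame, means: pd.Series, sds: pd.Series
) -> pd.DataFrame:
    """Scale new observations with stored training column statistics."""
    missing = [c for c in means.index if c not in data.columns]
    if missing:
        raise InputError(f"{len(missing)} model variables missing from new data")
    return (data[means.index] - means) / sds
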