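"""Composition-normalized statistics over template/product pairs.

The random template region of the construct is not perfectly equimolar, so
every composition-sensitive statistic is reweighted against a no-extension
control: position/base factors ``w(i, b) = 0.25 / f_control(i, b)`` make a
biased template look as if it were perfectly random with equal base ratios.
Each observation's weight is the product of the factors of its *template*
bases over exactly the positions entering the statistic (positions 1..L for
positional tables, the three window positions for trimer tables).  With a
uniform control all factors are 1 and every statistic reduces to its
unnormalized form.

Fidelity statistics (error frequency, mismatch spectrum, product-class
fractions) are unweighted by default — reweighting a fidelity estimate by
template composition would conflate bias with fidelity — with the weighted
variant available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .construct import MATCH, MISMATCH_LABELS, RNA_BASES, TemplateProductPair

_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}
_ENCODE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i

#: All 64 trimers in lexicographic (A<C<G<U) order.
TRIMERS = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)

TRIMER_WINDOW_123 = (1, 2, 3)
TRIMER_WINDOW_456 = (4, 5, 6)


class DegenerateControlError(ValueError):
    """Some template base is never observed at some position in the control."""


class EmptyTableError(ValueError):
    """No qualifying products for the requested statistic."""


# ---------------------------------------------------------------------------
# Vectorized pair container
# ---------------------------------------------------------------------------


class PairMatrix:
    """Columnar encoding of a pair set for vectorized statistics.

    Attributes
    ----------
    tpl : (n, T) int8 — template base codes (A=0, C=1, G=2, U=3), templating order
    prod : (n, T) int8 — product base codes, -1 beyond the product length
    length : (n,) int  — product lengths L
    mismatch : (n, T) bool — True where a covered position violates pairing
    """

    def __init__(self, tpl: np.ndarray, prod: np.ndarray, length: np.ndarray):
        self.tpl = tpl
        self.prod = prod
        self.length = length
        self.n, self.template_len = tpl.shape
        covered = np.arange(self.template_len)[None, :] < length[:, None]
        # complement code of b is 3 - b under the A,C,G,U encoding
        self.mismatch = covered & (prod != (3 - tpl))
        self.covered = covered

    @classmethod
    def from_pairs(cls, pairs: Sequence[TemplateProductPair]) -> "PairMatrix":
        if len(pairs) == 0:
            raise EmptyTableError("empty pair set")
        T = len(pairs[0].template)
        n = len(pairs)
        tpl = np.empty((n, T), dtype=np.int8)
        prod = np.full((n, T), -1, dtype=np.int8)
        length = np.empty(n, dtype=np.int64)
        for k, p in enumerate(pairs):
            if len(p.template) != T:
                raise ValueError("pairs have inconsistent template lengths")
            tpl[k] = _ENCODE[np.frombuffer(p.template.encode("ascii"), np.uint8)]
            L = len(p.product)
            length[k] = L
            if L:
                prod[k, :L] = _ENCODE[
                    np.frombuffer(p.product.encode("ascii"), np.uint8)
                ]
        if (tpl < 0).any() or (prod[prod != -1] < 0).any():
            raise ValueError("non-ACGU symbol in pair set")
        return cls(tpl, prod, length)

    @property
    def n_mismatches(self) -> np.ndarray:
        return self.mismatch.sum(axis=1)

    @property
    def is_complementary(self) -> np.ndarray:
        return (self.length > 0) & (self.n_mismatches == 0)


PairsLike = Union[PairMatrix, Sequence[TemplateProductPair]]


def _as_matrix(pairs: PairsLike) -> PairMatrix:
    return pairs if isinstance(pairs, PairMatrix) else PairMatrix.from_pairs(pairs)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-position, per-base reweighting factors from a no-extension control.

    ``w[i-1, b]`` is the weight applied to a template with base ``b`` at
    templating position ``i``; all entries are positive and a perfectly
    uniform control gives all ones.
    """

    w: np.ndarray  # (T, 4), positive

    def __post_init__(self) -> None:
        if self.w.ndim != 2 or self.w.shape[1] != 4:
            raise ValueError("normalization factors must be a T x 4 matrix")
        if not (self.w > 0).all():
            raise ValueError("normalization factors must be positive")

    @classmethod
    def uniform(cls, template_len: int) -> "NormalizationFactors":
        return cls(np.ones((template_len, 4)))

    @property
    def template_len(self) -> int:
        return self.w.shape[0]

    @property
    def is_uniform(self) -> bool:
        return bool(np.all(self.w == 1.0))

    def factor(self, position: int, base: str) -> float:
        """Weight for template base ``base`` at 1-based templating position."""
        return float(self.w[position - 1, _BASE_INDEX[base]])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.w,
            index=pd.RangeIndex(1, self.template_len + 1, name="position"),
            columns=list(RNA_BASES),
        )


def compute_normalization(
    control_pairs: PairsLike, template_len: Optional[int] = None
) -> NormalizationFactors:
    """Normalization factors from the templates of a no-extension control.

    ``f(i, b)`` is the fraction of control templates carrying base ``b`` at
    templating position ``i``; the factor is ``w(i, b) = 0.25 / f(i, b)``.
    Every base must be observed at every position, otherwise the control is
    degenerate and no finite factor exists.
    """
    pm = _as_matrix(control_pairs)
    if template_len is not None and pm.template_len != template_len:
        raise ValueError("control template length does not match template_len")
    counts = np.zeros((pm.template_len, 4))
    for b in range(4):
        counts[:, b] = (pm.tpl == b).sum(axis=0)
    if (counts == 0).any():
        i, b = np.argwhere(counts == 0)[0]
        raise DegenerateControlError(
            f"control never shows base {RNA_BASES[b]} at position {i + 1}"
        )
    f = counts / pm.n
    return NormalizationFactors(0.25 / f)


def pair_weight(
    pair: TemplateProductPair,
    norm: NormalizationFactors,
    positions: Iterable[int],
) -> float:
    """Product of template-base factors over the given 1-based positions."""
    w = 1.0
    for i in positions:
        w *= norm.factor(i, pair.template[i - 1])
    return w


def _weight_matrix(pm: PairMatrix, norm: Optional[NormalizationFactors]) -> np.ndarray:
    """(n, T) per-position template-base factors (ones when ``norm`` is None)."""
    if norm is None:
        return np.ones((pm.n, pm.template_len))
    if norm.template_len != pm.template_len:
        raise ValueError("normalization factors do not match template length")
    return norm.w[np.arange(pm.template_len)[None, :], pm.tpl]


# ---------------------------------------------------------------------------
# Positional frequency tables
# ---------------------------------------------------------------------------


@dataclass
class PositionalFrequencyTable:
    """Normalized product-base frequencies by position.

    ``F`` has one row per product position +1..+P and columns A, C, G, U;
    rows covered by at least one product sum to 1, uncovered rows are NaN.
    ``n_eff`` holds the (weighted) number of products covering each position.
    """

    F: pd.DataFrame
    n_eff: pd.Series
    product_class: str

    def mean_base_frequency(self, base: str, positions: Sequence[int]) -> float:
        """Arithmetic mean of F(i, base) over the given 1-based positions."""
        if len(positions) == 0:
            raise ValueError("empty position range")
        vals = self.F.loc[list(positions), base]
        if vals.isna().any():
            raise ValueError("requested positions include uncovered rows")
        return float(vals.mean())


def positional_frequencies(
    pairs: PairsLike,
    norm: Optional[NormalizationFactors] = None,
    product_class: str = "all",
) -> PositionalFrequencyTable:
    """Position-by-position product base composition.

    ``product_class='complementary'`` restricts to fully complementary
    (zero-mismatch) products, the class shown in the composition figures;
    ``'all'`` uses every extended product.  Each product's weight is the
    product of its template-base normalization factors over positions 1..L.
    """
    pm = _as_matrix(pairs)
    if product_class == "complementary":
        sel = pm.is_complementary
    elif product_class == "all":
        sel = pm.length > 0
    else:
        raise ValueError(f"unknown product class {product_class!r}")
    T = pm.template_len
    W = _weight_matrix(pm, norm)
    W = np.where(pm.covered, W, 1.0)
    full_w = W.prod(axis=1) * sel  # zero weight for unselected pairs

    F = np.full((T, 4), np.nan)
    n_eff = np.zeros(T)
    for i in range(T):
        covering = pm.length > i
        wts = full_w * covering
        denom = wts.sum()
        n_eff[i] = denom
        if denom > 0:
            for b in range(4):
                F[i, b] = wts[pm.prod[:, i] == b].sum() / denom
    idx = pd.RangeIndex(1, T + 1, name="position")
    return PositionalFrequencyTable(
        F=pd.DataFrame(F, index=idx, columns=list(RNA_BASES)),
        n_eff=pd.Series(n_eff, index=idx, name="n_eff"),
        product_class=product_class,
    )


def mean_base_frequency(
    table: PositionalFrequencyTable, base: str, positions: Sequence[int]
) -> float:
    """Mean frequency of ``base`` over 1-based ``positions`` of a table."""
    return table.mean_base_frequency(base, positions)


# ---------------------------------------------------------------------------
# Trimer tables
# ---------------------------------------------------------------------------


@dataclass
class TrimerTable:
    """Frequencies of the 64 product trimers in one position window.

    The ideal frequency under uniform usage is 1/64 ~ 0.016.  The median is
    taken over all 64 trimers (zeros included); the max/min fold-difference
    is over represented (nonzero) trimers only, reported to the nearest
    integer.
    """

    freq: pd.Series  # 64 entries indexed by trimer, sums to 1
    window: tuple[int, int, int]
    n_products: int

    @classmethod
    def from_frequencies(
        cls, freq: dict | pd.Series, window: tuple[int, int, int] = TRIMER_WINDOW_123
    ) -> "TrimerTable":
        """Build a table from a trimer->frequency mapping (zeros filled in)."""
        s = pd.Series(0.0, index=list(TRIMERS))
        for k, v in dict(freq).items():
            if k not in s.index:
                raise ValueError(f"not a trimer: {k!r}")
            s[k] = v
        if not np.isclose(s.sum(), 1.0, atol=1e-9):
            raise ValueError("trimer frequencies must sum to 1")
        return cls(freq=s, window=window, n_products=0)

    @property
    def median(self) -> float:
        return float(self.freq.median())

    @property
    def min_represented(self) -> float:
        nz = self.freq[self.freq > 0]
        return float(nz.min()) if len(nz) else float("nan")

    @property
    def max_frequency(self) -> float:
        return float(self.freq.max())

    @property
    def max_min_ratio(self) -> Optional[int]:
        """Fold difference between the most and least frequent represented
        trimers, nearest integer; None when no trimer is represented."""
        nz = self.freq[self.freq > 0]
        if len(nz) == 0:
            return None
        return int(round(float(nz.max()) / float(nz.min())))

    def summary(self) -> dict:
        return {
            "window": "-".join(str(i) for i in self.window),
            "n_products": self.n_products,
            "median": self.median,
            "min_represented": self.min_represented,
            "max": self.max_frequency,
            "max_min_ratio": self.max_min_ratio,
            "n_unrepresented": int((self.freq == 0).sum()),
        }


def trimer_frequencies(
    pairs: PairsLike,
    norm: Optional[NormalizationFactors] = None,
    window: tuple[int, int, int] = TRIMER_WINDOW_123,
) -> TrimerTable:
    """Trimer frequencies of complementary products over a position window.

    The window is positions 1-2-3 (products with L >= 3) or 4-5-6 (L >= 6).
    Each qualifying product contributes its product-base trimer with weight
    equal to the product of the template-base normalization factors over the
    three window positions.
    """
    if window not in (TRIMER_WINDOW_123, TRIMER_WINDOW_456):
        raise ValueError("window must be positions (1,2,3) or (4,5,6)")
    pm = _as_matrix(pairs)
    need = window[-1]
    sel = pm.is_complementary & (pm.length >= need)
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise EmptyTableError(f"no complementary products of length >= {need}")
    cols = [i - 1 for i in window]
    codes = pm.prod[np.ix_(sel.nonzero()[0], cols)].astype(np.int64)
    trimer_idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
    W = _weight_matrix(pm, norm)[np.ix_(sel.nonzero()[0], cols)]
    wts = W.prod(axis=1)
    totals = np.bincount(trimer_idx, weights=wts, minlength=64)
    freq = totals / totals.sum()
    return TrimerTable(
        freq=pd.Series(freq, index=list(TRIMERS)), window=window, n_products=n_sel
    )


# ---------------------------------------------------------------------------
# Fidelity statistics
# ---------------------------------------------------------------------------


def error_frequency(
    pairs: PairsLike, norm: Optional[NormalizationFactors] = None
) -> float:
    """Fraction of incorporated product bases violating complementarity.

    Computed over all extended products.  Unweighted by default; passing
    ``norm`` gives the composition-weighted variant (each product's bases
    weighted by its positions-1..L template factors).
    """
    pm = _as_matrix(pairs)
    ext = pm.length > 0
    if not ext.any():
        raise EmptyTableError("no extended products")
    if norm is None:
        return float(pm.mismatch.sum() / pm.length.sum())
    W = np.where(pm.covered, _weight_matrix(pm, norm), 1.0)
    full_w = W.prod(axis=1)
    num = (full_w * pm.mismatch.sum(axis=1)).sum()
    den = (full_w * pm.length).sum()
    return float(num / den)


@dataclass
class MismatchSpectrum:
    """Frequencies of the 12 template:product mismatch types by position.

    Cells are normalized over all observed mismatches (total 1 when any
    mismatch exists, all-zero otherwise).  ``position_marginal`` sums the
    spectrum over mismatch types; ``type_marginal`` over positions.
    """

    M: pd.DataFrame  # 12 x P, rows MISMATCH_LABELS, columns positions 1..P
    n_mismatches: int

    @property
    def position_marginal(self) -> pd.Series:
        return self.M.sum(axis=0)

    @property
    def type_marginal(self) -> pd.Series:
        return self.M.sum(axis=1)


def mismatch_spectrum(pairs: PairsLike) -> MismatchSpectrum:
    """Joint distribution of mismatch type (template:product) and position."""
    pm = _as_matrix(pairs)
    T = pm.template_len
    counts = np.zeros((12, T))
    label_of = {}
    for t in range(4):
        for p in range(4):
            if p != 3 - t:
                label_of[(t, p)] = f"{RNA_BASES[t]}:{RNA_BASES[p]}"
    row_of = {lbl: r for r, lbl in enumerate(MISMATCH_LABELS)}
    rows, cols = np.nonzero(pm.mismatch)
    for k, i in zip(rows, cols):
        lbl = label_of[(int(pm.tpl[k, i]), int(pm.prod[k, i]))]
        counts[row_of[lbl], i] += 1
    total = counts.sum()
    M = counts / total if total > 0 else counts
    return MismatchSpectrum(
        M=pd.DataFrame(
            M,
            index=list(MISMATCH_LABELS),
            columns=pd.RangeIndex(1, T + 1, name="position"),
        ),
        n_mismatches=int(total),
    )


def product_class_fractions(pairs: PairsLike) -> dict:
    """Complementary / multi-mismatch / terminal-mismatch fractions.

    ``complementary_fraction`` is over extended products; the
    ``multi_mismatch_fraction`` conditions on products with at least one
    mismatch (fraction with more than one); the ``terminal_mismatch_fraction``
    conditions on products with exactly one mismatch (fraction whose mismatch
    is the last base added).  Undefined conditionals are reported as None.
    """
    pm = _as_matrix(pairs)
    ext = pm.length > 0
    n_ext = int(ext.sum())
    if n_ext == 0:
        raise EmptyTableError("no extended products")
    nm = pm.n_mismatches
    complementary = float((ext & (nm == 0)).sum() / n_ext)

    with_mm = ext & (nm >= 1)
    multi = float((nm[with_mm] > 1).mean()) if with_mm.any() else None

    single = ext & (nm == 1)
    if single.any():
        idx = single.nonzero()[0]
        # the one mismatch sits at position L iff the last covered call is a mismatch
        last_pos = pm.length[idx] - 1
        terminal = float(pm.mismatch[idx, last_pos].mean())
    else:
        terminal = None
    return {
        "complementary_fraction": complementary,
        "multi_mismatch_fraction": multi,
        "terminal_mismatch_fraction": terminal,
    }


# ---------------------------------------------------------------------------
# Yield and length statistics
# ---------------------------------------------------------------------------


def yield_and_lengths(pairs: PairsLike) -> dict:
    """Extension yield, product-length distribution and cumulative incorporation.

    ``yield_fraction`` is the fraction of all molecules (unextended primers
    included) with L >= 1.  ``cumulative_incorporation`` gives, per position
    i, the fraction of all molecules extended at least to i, split by the
    call at position i itself; it is non-increasing in i and its first value
    equals the yield.
    """
    pm = _as_matrix(pairs)
    T = pm.template_len
    n = pm.n
    yield_fraction = float((pm.length >= 1).sum() / n)
    length_counts = np.bincount(pm.length, minlength=T + 1)
    length_distribution = pd.Series(
        length_counts / n,
        index=pd.RangeIndex(0, T + 1, name="length"),
        name="fraction",
    )
    total = np.empty(T)
    correct = np.empty(T)
    for i in range(T):
        reach = pm.length > i
        total[i] = reach.sum() / n
        correct[i] = (reach & ~pm.mismatch[:, i]).sum() / n
    cum = pd.DataFrame(
        {"total": total, "correct": correct, "incorrect": total - correct},
        index=pd.RangeIndex(1, T + 1, name="position"),
    )
    return {
        "yield_fraction": yield_fraction,
        "length_distribution": length_distribution,
        "cumulative_incorporation": cum,
    }
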