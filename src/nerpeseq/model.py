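"""Model/results interface over a set of template/product pairs.

:class:`PrimerExtensionModel` holds the extracted pairs of one experiment
together with its no-extension control; :meth:`~PrimerExtensionModel.fit`
computes the normalization factors and every product statistic in one pass
and returns a :class:`PrimerExtensionResults` carrying the tables, the
scalar summaries, a text ``summary()`` and ``save()``/plot helpers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .construct import TemplateProductPair
from . import stats as _st
from .reads import read_pairs_tsv

SUMMARY_SCHEMA = "nerpeseq-summary-1"


class PrimerExtensionModel:
    """Product statistics of one primer-extension experiment.

    Parameters
    ----------
    pairs : sequence of TemplateProductPair
        Extracted pairs of the experiment (unextended primers included —
        yields are undefined without them).
    control_pairs : sequence of TemplateProductPair, optional
        Pairs from the matching no-extension control; their templates define
        the composition-normalization factors.
    normalize : bool
        Apply control-based normalization to composition statistics.
        Requires ``control_pairs``.
    """

    def __init__(
        self,
        pairs: Sequence[TemplateProductPair],
        control_pairs: Optional[Sequence[TemplateProductPair]] = None,
        normalize: bool = True,
    ):
        if len(pairs) == 0:
            raise ValueError("no pairs to analyse")
        if normalize and control_pairs is None:
            raise ValueError("normalize=True requires control_pairs")
        self.pairs = list(pairs)
        self.control_pairs = list(control_pairs) if control_pairs is not None else None
        self.normalize = normalize

    @classmethod
    def from_tsv(
        cls,
        pairs_path: str | Path,
        control_path: Optional[str | Path] = None,
        normalize: bool = True,
    ) -> "PrimerExtensionModel":
        """Build a model from pair TSVs written by the extraction step."""
        pairs = read_pairs_tsv(pairs_path)
        control = read_pairs_tsv(control_path) if control_path is not None else None
        return cls(pairs, control, normalize=normalize)

    def fit(self) -> "PrimerExtensionResults":
        pm = _st.PairMatrix.from_pairs(self.pairs)
        if self.normalize:
            cm = _st.PairMatrix.from_pairs(self.control_pairs)
            norm = _st.compute_normalization(cm, template_len=pm.template_len)
        else:
            norm = None
        return PrimerExtensionResults(self, pm, norm)


class PrimerExtensionResults:
    """Fitted statistics bundle for one experiment.

    Attributes
    ----------
    norm : NormalizationFactors or None
    positional_all, positional_complementary : PositionalFrequencyTable
    trimer_123, trimer_456 : TrimerTable or None (None when no product qualifies)
    spectrum : MismatchSpectrum
    yield_fraction, error_frequency : float
    length_distribution : pandas.Series over L = 0..T
    cumulative_incorporation : pandas.DataFrame (total/correct/incorrect by position)
    """

    def __init__(self, model, pm: _st.PairMatrix, norm):
        self.model = model
        self.norm = norm
        self.n_pairs = pm.n
        self.template_len = pm.template_len

        self.positional_all = _st.positional_frequencies(pm, norm, "all")
        self.positional_complementary = _st.positional_frequencies(
            pm, norm, "complementary"
        )
        self.trimer_123 = self._try_trimers(pm, norm, _st.TRIMER_WINDOW_123)
        self.trimer_456 = self._try_trimers(pm, norm, _st.TRIMER_WINDOW_456)
        self.spectrum = _st.mismatch_spectrum(pm)

        yl = _st.yield_and_lengths(pm)
        self.yield_fraction = yl["yield_fraction"]
        self.length_distribution = yl["length_distribution"]
        self.cumulative_incorporation = yl["cumulative_incorporation"]

        self.n_extended = int((pm.length > 0).sum())
        if self.n_extended:
            self.error_frequency = _st.error_frequency(pm)
            self.error_frequency_weighted = (
                _st.error_frequency(pm, norm) if norm is not None else None
            )
            cf = _st.product_class_fractions(pm)
        else:
            self.error_frequency = None
            self.error_frequency_weighted = None
            cf = {
                "complementary_fraction": None,
                "multi_mismatch_fraction": None,
                "terminal_mismatch_fraction": None,
            }
        self.complementary_fraction = cf["complementary_fraction"]
        self.multi_mismatch_fraction = cf["multi_mismatch_fraction"]
        self.terminal_mismatch_fraction = cf["terminal_mismatch_fraction"]

    @staticmethod
    def _try_trimers(pm, norm, window):
        try:
            return _st.trimer_frequencies(pm, norm, window)
        except _st.EmptyTableError:
            return None

    # -- reporting -----------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable summary of all scalar statistics."""

        def mean_freq(table, base, upto):
            try:
                return table.mean_base_frequency(base, list(range(1, upto + 1)))
            except (ValueError, KeyError):
                return None

        d = {
            "schema": SUMMARY_SCHEMA,
            "n_pairs": self.n_pairs,
            "n_extended": self.n_extended,
            "template_len": self.template_len,
            "normalized": self.norm is not None,
            "yield_fraction": self.yield_fraction,
            "error_frequency": self.error_frequency,
            "error_frequency_weighted": self.error_frequency_weighted,
            "complementary_fraction": self.complementary_fraction,
            "multi_mismatch_fraction": self.multi_mismatch_fraction,
            "terminal_mismatch_fraction": self.terminal_mismatch_fraction,
            "n_mismatches": self.spectrum.n_mismatches,
            "mean_freq_positions_1_4": {
                b: mean_freq(self.positional_complementary, b, 4) for b in "ACGU"
            },
        }
        for name, table in (("trimer_123", self.trimer_123),
                            ("trimer_456", self.trimer_456)):
            d[name] = table.summary() if table is not None else None
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def summary(self) -> str:
        """Human-readable summary table (frequencies at 3 decimals)."""

        def fmt(v):
            if v is None:
                return "undefined"
            return f"{v:.3f}" if isinstance(v, float) else str(v)

        rows = [
            ("molecules analysed", self.n_pairs),
            ("extended products", self.n_extended),
            ("yield (fraction extended)", fmt(self.yield_fraction)),
            ("error frequency", fmt(self.error_frequency)),
            ("complementary fraction", fmt(self.complementary_fraction)),
            (">1-mismatch fraction", fmt(self.multi_mismatch_fraction)),
            ("terminal-mismatch fraction", fmt(self.terminal_mismatch_fraction)),
            ("normalized to control", "yes" if self.norm is not None else "no"),
        ]
        for name, table in (("trimer 1-2-3", self.trimer_123),
                            ("trimer 4-5-6", self.trimer_456)):
            if table is not None:
                s = table.summary()
                rows.append((f"{name} median", fmt(s["median"])))
                rows.append((f"{name} max/min ratio", s["max_min_ratio"]))
        width = max(len(r[0]) for r in rows) + 2
        lines = ["Primer extension product statistics",
                 "=" * (width + 12)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write all tables (TSV) and the JSON summary into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def tsv(name, df):
            p = outdir / f"{name}.tsv"
            df.to_csv(p, sep="\t")
            paths[name] = str(p)

        tsv("positional_all", self.positional_all.F)
        tsv("positional_complementary", self.positional_complementary.F)
        if self.trimer_123 is not None:
            tsv("trimer_123", self.trimer_123.freq.rename("frequency"))
        if self.trimer_456 is not None:
            tsv("trimer_456", self.trimer_456.freq.rename("frequency"))
        tsv("mismatch_spectrum", self.spectrum.M)
        tsv("length_distribution", self.length_distribution)
        tsv("cumulative_incorporation", self.cumulative_incorporation)
        if self.norm is not None:
            tsv("normalization_factors", self.norm.as_dataframe())
        p = outdir / "summary.json"
        p.write_text(self.to_json())
        paths["summary"] = str(p)
        return paths

    # -- plotting -------------------------------------------------------------

    def plot_positional(self, product_class: str = "complementary", ax=None):
        """Stacked-bar product base composition by position."""
        import matplotlib.pyplot as plt

        table = (self.positional_complementary if product_class == "complementary"
                 else self.positional_all)
        if ax is None:
            _, ax = plt.subplots()
        table.F.plot.bar(stacked=True, ax=ax, width=0.9)
        ax.set_ylabel("frequency")
        ax.set_xlabel("product position")
        ax.set_title(f"product base composition ({product_class})")
        return ax

    def plot_trimers(self, window: str = "123", ax=None):
        """Trimer frequencies ordered by trimer identity."""
        import matplotlib.pyplot as plt

        table = self.trimer_123 if window == "123" else self.trimer_456
        if table is None:
            raise ValueError(f"no trimer table for window {window}")
        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        table.freq.plot.bar(ax=ax, width=0.9)
        ax.axhline(1 / 64, color="grey", ls="--", lw=0.8, label="ideal 1/64")
        ax.set_ylabel("frequency")
        ax.legend()
        return ax

    def plot_cumulative(self, ax=None):
        """Cumulative correct/incorrect incorporation by position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cum = self.cumulative_incorporation
        ax.bar(cum.index, cum["correct"], label="correct")
        ax.bar(cum.index, cum["incorrect"], bottom=cum["correct"], label="incorrect")
        ax.set_xlabel("product position")
        ax.set_ylabel("fraction of molecules extended ≥ position")
        ax.legend()
        return ax
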