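"""Hairpin construct geometry, the RNA alphabet, and template/product pairing.

The sequencing construct is a self-priming RNA hairpin: a fixed 5' handle,
a random-sequence template region (``template_len`` bases, 18 by default),
a hairpin loop, and a fixed primer whose 3' terminus folds back to pair
adjacent to the template.  Nonenzymatic extension of that primer copies the
template in cis; after the reaction an RT handle is ligated to the product
3' end so the whole molecule can be read out as

    5'- handle5 | template | loop | primer | product | rt_handle -3'

All statistics are indexed in *templating order*: template base ``t_1``
directs product position +1 (the first base added to the primer), so the
templating-order template is the reverse of the template region as written
5'->3' in the molecule.  The product is antiparallel to the template, and
position +i is a Watson-Crick match when ``p_i == complement(t_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

RNA_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_COMPLEMENT_TABLE = str.maketrans("ACGU", "UGCA")

#: Sentinel used in per-position calls for a correct (Watson-Crick) incorporation.
MATCH = "M"

#: The 12 possible mismatch labels, written template:product.
MISMATCH_LABELS = tuple(
    f"{t}:{p}" for t in RNA_BASES for p in RNA_BASES if p != _COMPLEMENT[t]
)


class AlphabetError(ValueError):
    """A symbol outside the RNA alphabet {A, C, G, U} was encountered."""


class ProductOverrunError(ValueError):
    """A product is longer than the template region it was copied from."""


def complement(base: str) -> str:
    """Watson-Crick partner of a single RNA base (A<->U, G<->C)."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"not an RNA base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence."""
    for ch in seq:
        if ch not in _COMPLEMENT:
            raise AlphabetError(f"not an RNA base: {ch!r}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def call_matches(template: str, product: str) -> tuple[str, ...]:
    """Per-position match/mismatch calls for a product against its template.

    Both sequences are given in templating order / order of addition, so
    position i of the product was directed by position i of the template.
    Call i is :data:`MATCH` when ``product[i] == complement(template[i])``,
    otherwise the mismatch label ``"template:product"`` (e.g. ``"A:G"`` means
    template A directed product G).

    Raises
    ------
    ProductOverrunError
        If the product is longer than the template.
    AlphabetError
        If either sequence contains a non-RNA symbol.
    """
    if len(product) > len(template):
        raise ProductOverrunError(
            f"product length {len(product)} exceeds template length {len(template)}"
        )
    calls = []
    for t, p in zip(template, product):
        if t not in _COMPLEMENT:
            raise AlphabetError(f"not an RNA base: {t!r}")
        if p not in _COMPLEMENT:
            raise AlphabetError(f"not an RNA base: {p!r}")
        calls.append(MATCH if p == _COMPLEMENT[t] else f"{t}:{p}")
    return tuple(calls)


def _check_rna(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"fixed region {name!r} must be nonempty")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise AlphabetError(f"fixed region {name!r} contains non-RNA symbols {bad}")


@dataclass(frozen=True)
class ConstructSpec:
    """Layout of the self-priming hairpin construct.

    Parameters
    ----------
    handle5 : str
        Fixed region at the molecule 5' end.
    template_len : int
        Length of the random-sequence template region (>= 3 so trimer
        statistics are defined).
    loop : str
        Hairpin loop between template and primer.
    primer : str
        Self-priming 3' segment; the product occupies positions immediately
        3' of it, antiparallel to the template.
    rt_handle : str
        Handle ligated to the product 3' end that templates reverse
        transcription.
    max_region_mismatches : int
        Substitutions tolerated when anchoring each fixed region in a read.
    """

    handle5: str = "ACGGUCAUUCAG"
    template_len: int = 18
    loop: str = "CUUCGGAC"
    primer: str = "GGACUAGCAU"
    rt_handle: str = "CGUAGCCAUUCG"
    max_region_mismatches: int = 1

    def __post_init__(self) -> None:
        for name in ("handle5", "loop", "primer", "rt_handle"):
            _check_rna(name, getattr(self, name))
        if self.template_len < 3:
            raise ValueError("template_len must be >= 3 (trimer statistics require it)")
        if self.max_region_mismatches < 0:
            raise ValueError("max_region_mismatches must be >= 0")

    # -- insert coordinates (0-based, half-open, molecule orientation) -------

    @property
    def template_start(self) -> int:
        return len(self.handle5)

    @property
    def template_end(self) -> int:
        return self.template_start + self.template_len

    @property
    def loop_start(self) -> int:
        return self.template_end

    @property
    def primer_start(self) -> int:
        return self.loop_start + len(self.loop)

    @property
    def product_start(self) -> int:
        """Insert offset of product position +1."""
        return self.primer_start + len(self.primer)

    @property
    def fixed_len(self) -> int:
        """Insert length excluding the (variable-length) product."""
        return (
            len(self.handle5)
            + self.template_len
            + len(self.loop)
            + len(self.primer)
            + len(self.rt_handle)
        )

    @property
    def min_insert_len(self) -> int:
        return self.fixed_len

    @property
    def max_insert_len(self) -> int:
        return self.fixed_len + self.template_len

    def assemble_insert(self, template_templating_order: str, product: str) -> str:
        """Build the full insert for one molecule.

        ``template_templating_order`` is given with t_1 first; the insert
        carries the template in molecule orientation (5'->3'), which is the
        reverse.
        """
        if len(template_templating_order) != self.template_len:
            raise ValueError("template length does not match construct spec")
        if len(product) > self.template_len:
            raise ProductOverrunError("product longer than template region")
        return (
            self.handle5
            + template_templating_order[::-1]
            + self.loop
            + self.primer
            + product
            + self.rt_handle
        )

    def to_dict(self) -> dict:
        return {
            "handle5": self.handle5,
            "template_len": self.template_len,
            "loop": self.loop,
            "primer": self.primer,
            "rt_handle": self.rt_handle,
            "max_region_mismatches": self.max_region_mismatches,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstructSpec":
        known = {
            "handle5",
            "template_len",
            "loop",
            "primer",
            "rt_handle",
            "max_region_mismatches",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown construct fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstructSpec":
        """Load a construct definition from a YAML config file.

        The file holds either the construct mapping at top level or under a
        ``construct:`` key.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"construct config {path} is not a mapping")
        if "construct" in data:
            data = data["construct"]
        return cls.from_dict(data)


@dataclass(frozen=True)
class TemplateProductPair:
    """One molecule's template and extension product, in templating order.

    ``template[i]`` (0-based) is the base directing product position +(i+1);
    ``product`` is in order of addition (+1 first).  ``calls`` classifies each
    product position as :data:`MATCH` or a ``template:product`` mismatch label.
    A product of length zero is an unextended primer.
    """

    template: str
    product: str
    calls: tuple[str, ...] = field(default=())
    source_id: str = ""

    @classmethod
    def from_sequences(
        cls, template: str, product: str, source_id: str = ""
    ) -> "TemplateProductPair":
        """Build a pair, computing the match calls."""
        return cls(
            template=template,
            product=product,
            calls=call_matches(template, product),
            source_id=source_id,
        )

    @property
    def length(self) -> int:
        """Product length L (number of incorporated bases)."""
        return len(self.product)

    @property
    def is_extended(self) -> bool:
        return len(self.product) > 0

    @property
    def n_mismatches(self) -> int:
        return sum(1 for c in self.calls if c != MATCH)

    @property
    def is_complementary(self) -> bool:
        """True for a fully complementary (zero-mismatch) extended product."""
        return self.is_extended and self.n_mismatches == 0

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        """1-based product positions carrying a mismatch."""
        return tuple(i + 1 for i, c in enumerate(self.calls) if c != MATCH)
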