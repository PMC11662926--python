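"""Raw paired reads -> validated template/product pairs.

Processing steps per read pair:

1. quality filtering on Phred scores (mean and per-base thresholds, inclusive);
2. merging the overlapping forward and reverse mates into a consensus insert,
   rejecting pairs whose overlap disagrees at more than ``max_disagreements``
   positions (at a retained disagreement the higher-quality base wins);
3. anchoring the fixed construct regions (5' handle, loop, primer, RT handle)
   by substitution-only (Hamming) matching with a per-region tolerance;
4. extracting the template window (re-indexed into templating order) and the
   product window (order of addition) as a
   :class:`~nerpeseq.construct.TemplateProductPair`.

Every rejection is tallied in a :class:`FilterReport`; counts are conserved
(reasons + accepted = total input).  Coordinates are 0-based half-open
throughout; the only orientation flip happens inside :func:`extract_pair`.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .construct import (
    RNA_BASES,
    ConstructSpec,
    TemplateProductPair,
    reverse_complement,
)

_DNA_TO_RNA = str.maketrans("Tt", "Uu")

#: Rejection reasons, in the order they are applied.
REJECT_REASONS = (
    "low_quality",
    "mates_disagree",
    "fixed_region_mismatch",
    "template_has_ambiguity",
    "product_overrun",
)


class FastqParseError(ValueError):
    """Malformed FASTQ record (e.g. sequence/quality length mismatch)."""


@dataclass
class ReadPair:
    """One paired-end read: sequences plus per-base Phred scores."""

    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: np.ndarray
    rev_qual: np.ndarray

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise FastqParseError(
                f"read {self.id}: sequence and quality lengths differ"
            )


@dataclass
class FilterReport:
    """Tally of accepted reads and per-reason rejections."""

    accepted: int = 0
    rejected: dict = field(
        default_factory=lambda: {r: 0 for r in REJECT_REASONS}
    )

    @property
    def total(self) -> int:
        return self.accepted + sum(self.rejected.values())

    def reject(self, reason: str) -> None:
        self.rejected[reason] += 1

    def to_dict(self) -> dict:
        return {"total": self.total, "accepted": self.accepted, **self.rejected}

    def to_text(self) -> str:
        lines = [f"reads total      {self.total}", f"reads accepted   {self.accepted}"]
        for reason in REJECT_REASONS:
            lines.append(f"{reason:<17}{self.rejected[reason]}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# FASTQ input
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_paired_fastq(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    """Iterate read pairs from two FASTQ files (plain or gzipped, Phred+33).

    Sequences are uppercased and T is mapped to U: the reads are cDNA-derived
    but all downstream work is in the RNA alphabet.
    """
    with _open_text(r1) as fh1, _open_text(r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, seq1, q1), (id2, seq2, q2) in zip(it1, it2):
            rid = id1.split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            yield ReadPair(
                id=rid,
                fwd_seq=seq1.upper().translate(_DNA_TO_RNA),
                rev_seq=seq2.upper().translate(_DNA_TO_RNA),
                fwd_qual=np.frombuffer(q1.encode("ascii"), dtype=np.uint8).astype(
                    np.int16
                )
                - 33,
                rev_qual=np.frombuffer(q2.encode("ascii"), dtype=np.uint8).astype(
                    np.int16
                )
                - 33,
            )


# ---------------------------------------------------------------------------
# Per-read operations
# ---------------------------------------------------------------------------


def quality_filter(
    pair: ReadPair, min_mean_q: float = 30.0, min_base_q: int = 20
) -> Optional[str]:
    """Return ``None`` if the pair passes, else the rejection reason.

    A pair fails when either mate's mean Phred score is below ``min_mean_q``
    or any base falls below ``min_base_q``.  Both thresholds are inclusive:
    a mean exactly at ``min_mean_q`` passes.
    """
    for q in (pair.fwd_qual, pair.rev_qual):
        if q.size == 0 or q.min() < 0 or q.max() > 60:
            raise FastqParseError(f"read {pair.id}: Phred scores outside 0-60")
        if q.mean() < min_mean_q or q.min() < min_base_q:
            return "low_quality"
    return None


def merge_mates(
    pair: ReadPair,
    max_disagreements: int = 0,
    candidate_offsets: Optional[Sequence[int]] = None,
    min_overlap: int = 10,
) -> Optional[str]:
    """Merge overlapping mates into a consensus insert (forward orientation).

    The reverse mate is reverse-complemented and slid along the forward mate;
    the offset with the fewest overlap disagreements wins.  ``None`` is
    returned when no overlap of at least ``min_overlap`` bases agrees within
    ``max_disagreements``.  At a retained disagreement the higher-quality base
    is kept (the forward base on a quality tie).

    ``candidate_offsets`` restricts the search to the offsets consistent with
    the construct's possible insert lengths (offset = insert length minus
    reverse-read length); callers that know the construct should pass them.
    """
    fwd = pair.fwd_seq
    rcrev = reverse_complement(pair.rev_seq)
    rev_qual_rc = pair.rev_qual[::-1]
    nf, nr = len(fwd), len(rcrev)

    if candidate_offsets is None:
        offsets: Iterable[int] = range(0, nf - min_overlap + 1)
    else:
        offsets = [d for d in candidate_offsets if 0 <= d <= nf - min_overlap]

    fwd_b = np.frombuffer(fwd.encode("ascii"), dtype=np.uint8)
    rcrev_b = np.frombuffer(rcrev.encode("ascii"), dtype=np.uint8)

    best_d = -1
    best_mm = None
    for d in offsets:
        ov = min(nf - d, nr)
        if ov < min_overlap:
            continue
        # fast path: exact agreement
        if fwd[d : d + ov] == rcrev[:ov]:
            best_d, best_mm = d, 0
            break
        mm = int(np.count_nonzero(fwd_b[d : d + ov] != rcrev_b[:ov]))
        if best_mm is None or mm < best_mm:
            best_d, best_mm = d, mm
    if best_mm is None or best_mm > max_disagreements:
        return None

    d = best_d
    ov = min(nf - d, nr)
    if best_mm == 0:
        mid = fwd[d : d + ov]
    else:
        mid_chars = []
        for i in range(ov):
            a, b = fwd[d + i], rcrev[i]
            if a == b or pair.fwd_qual[d + i] >= rev_qual_rc[i]:
                mid_chars.append(a)
            else:
                mid_chars.append(b)
        mid = "".join(mid_chars)
    return fwd[:d] + mid + rcrev[ov:]


@dataclass(frozen=True)
class RegionCoords:
    """Half-open 0-based windows of the variable regions in a merged insert."""

    template: tuple[int, int]
    product: tuple[int, int]


class FixedRegionError(ValueError):
    """A fixed construct region could not be anchored within tolerance."""


class AmbiguousBaseError(ValueError):
    """The template or product window contains a non-ACGU symbol."""


def _hamming_within(a: str, b: str, tol: int) -> bool:
    if a == b:
        return True
    if tol == 0:
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > tol:
                return False
    return True


def locate_regions(
    merged_seq: str, spec: ConstructSpec, search: int = 3
) -> RegionCoords:
    """Anchor the fixed regions of a merged insert and return window coordinates.

    Each fixed region must match at its expected offset (the whole layout may
    shift by up to ``search`` nt) with at most ``spec.max_region_mismatches``
    substitutions; no indels are considered.  The RT handle is searched over
    all admissible product lengths; a handle found beyond ``template_len``
    product bases raises :class:`~nerpeseq.construct.ProductOverrunError`.
    """
    from .construct import ProductOverrunError

    tol = spec.max_region_mismatches
    n = len(merged_seq)
    for s in range(0, search + 1):
        if s + len(spec.handle5) > n:
            break
        if not _hamming_within(
            merged_seq[s : s + len(spec.handle5)], spec.handle5, tol
        ):
            continue
        t0 = s + len(spec.handle5)
        t1 = t0 + spec.template_len
        loop0 = t1
        loop1 = loop0 + len(spec.loop)
        if loop1 > n or not _hamming_within(
            merged_seq[loop0:loop1], spec.loop, tol
        ):
            continue
        prim1 = loop1 + len(spec.primer)
        if prim1 > n or not _hamming_within(
            merged_seq[loop1:prim1], spec.primer, tol
        ):
            continue
        # product window: scan admissible lengths for the RT handle
        rt_len = len(spec.rt_handle)
        found_L = None
        best_mm = None
        for L in range(0, spec.template_len + search + 1):
            r0 = prim1 + L
            if r0 + rt_len > n:
                break
            window = merged_seq[r0 : r0 + rt_len]
            if window == spec.rt_handle:
                found_L, best_mm = L, 0
                break
            if tol > 0:
                mm = sum(1 for x, y in zip(window, spec.rt_handle) if x != y)
                if mm <= tol and (best_mm is None or mm < best_mm):
                    found_L, best_mm = L, mm
        if found_L is None:
            continue
        if found_L > spec.template_len:
            raise ProductOverrunError(
                f"product window of length {found_L} exceeds template_len"
            )
        return RegionCoords(template=(t0, t1), product=(prim1, prim1 + found_L))
    raise FixedRegionError("fixed regions not found within tolerance")


def extract_pair(
    merged_seq: str, coords: RegionCoords, spec: ConstructSpec, source_id: str = ""
) -> TemplateProductPair:
    """Extract the template/product pair from a located insert.

    The template window is re-indexed into templating order (the base adjacent
    to the primer becomes t_1, i.e. the window is reversed); the product
    window is already in order of addition.  Windows containing a non-ACGU
    symbol raise :class:`AmbiguousBaseError`.
    """
    t0, t1 = coords.template
    p0, p1 = coords.product
    template_mol = merged_seq[t0:t1]
    product = merged_seq[p0:p1]
    if set(template_mol) - set(RNA_BASES) or set(product) - set(RNA_BASES):
        raise AmbiguousBaseError("ambiguous base in template or product window")
    return TemplateProductPair.from_sequences(
        template=template_mol[::-1], product=product, source_id=source_id
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def process_read_pairs(
    read_pairs: Iterable[ReadPair],
    spec: ConstructSpec,
    min_mean_q: float = 30.0,
    min_base_q: int = 20,
    max_disagreements: int = 0,
    search: int = 3,
) -> tuple[list[TemplateProductPair], FilterReport]:
    """Run the full filter/merge/locate/extract chain over read pairs.

    If the fixed regions are not found in the merged insert, its reverse
    complement is tried before rejecting, so a mate-swapped pair yields the
    identical extraction.
    """
    from .construct import ProductOverrunError

    report = FilterReport()
    pairs: list[TemplateProductPair] = []

    for rp in read_pairs:
        reason = quality_filter(rp, min_mean_q=min_mean_q, min_base_q=min_base_q)
        if reason is not None:
            report.reject(reason)
            continue
        candidates = sorted(
            {
                spec.fixed_len + L - len(rp.rev_seq)
                for L in range(0, spec.template_len + 1)
            }
        )
        merged = merge_mates(
            rp, max_disagreements=max_disagreements, candidate_offsets=candidates
        )
        if merged is None:
            # fall back to an unconstrained overlap scan before rejecting
            merged = merge_mates(rp, max_disagreements=max_disagreements)
        if merged is None:
            report.reject("mates_disagree")
            continue

        coords = None
        overrun = False
        for insert in (merged, _safe_revcomp(merged)):
            if insert is None:
                continue
            try:
                coords = locate_regions(insert, spec, search=search)
                merged = insert
                break
            except FixedRegionError:
                continue
            except ProductOverrunError:
                overrun = True
                merged = insert
                break
        if overrun:
            report.reject("product_overrun")
            continue
        if coords is None:
            report.reject("fixed_region_mismatch")
            continue

        try:
            pair = extract_pair(merged, coords, spec, source_id=rp.id)
        except AmbiguousBaseError:
            report.reject("template_has_ambiguity")
            continue
        pairs.append(pair)
        report.accepted += 1

    return pairs, report


def _safe_revcomp(seq: str) -> Optional[str]:
    try:
        return reverse_complement(seq)
    except Exception:
        return None


def process_fastq(
    r1: str | Path,
    r2: str | Path,
    spec: ConstructSpec,
    **kwargs,
) -> tuple[list[TemplateProductPair], FilterReport]:
    """Convenience wrapper: :func:`read_paired_fastq` + :func:`process_read_pairs`."""
    return process_read_pairs(read_paired_fastq(r1, r2), spec, **kwargs)


# ---------------------------------------------------------------------------
# Pair TSV round trip
# ---------------------------------------------------------------------------

_TSV_HEADER = "id\ttemplate\tproduct\tlength\tcalls"


def write_pairs_tsv(pairs: Iterable[TemplateProductPair], path: str | Path) -> None:
    """Write pairs to TSV: id, template (templating order), product, L, calls."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for p in pairs:
            fh.write(
                f"{p.source_id}\t{p.template}\t{p.product}\t{p.length}\t"
                f"{','.join(p.calls)}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[TemplateProductPair]:
    """Read pairs written by :func:`write_pairs_tsv`; calls are recomputed."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected pair TSV header in {path}")
        for line in fh:
            pid, template, product, _length, _calls = line.rstrip("\n").split("\t")
            pairs.append(
                TemplateProductPair.from_sequences(template, product, source_id=pid)
            )
    return pairs
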