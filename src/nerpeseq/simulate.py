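"""Ground-truth-tagged synthetic reads emulating a primer-extension experiment.

Each simulated molecule is a hairpin construct with a random template:

* the template is drawn position-by-position from ``template_composition``;
* with probability ``extension_prob`` the primer is extended; the product
  length is drawn from a truncated geometric distribution (or an explicit
  pmf), capped at the template length;
* each incorporated base is drawn from the 4x4 ``base_bias`` matrix
  ``B(t, p)`` — row t gives the distribution of the product base opposite
  template base t, so the diagonal-complement mass is the correct-incorporation
  probability and the off mass encodes both the error rate and the mismatch
  spectrum;
* with probability ``ligation_prob`` a contiguous block of ``ligation_len``
  further bases is appended whose per-base mismatch rate is
  ``ligation_error_rate``, emulating the multi-mismatch products that
  oligonucleotide ligation contributes;
* reads are rendered from the assembled insert with independent per-base
  substitution errors at ``seq_error_rate`` on each mate and constant
  Phred quality.

The matching no-extension control is the same generative model with the
extension probability forced to zero.  All randomness flows from one seed;
identical parameters give byte-identical FASTQ output.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .construct import ConstructSpec, TemplateProductPair, reverse_complement

_DECODE = np.frombuffer(b"ACGU", dtype=np.uint8)
_RNA_TO_DNA = str.maketrans("U", "T")


def _default_base_bias(error_rate: float = 0.063) -> np.ndarray:
    """Correct incorporation with probability 1 - error_rate, uniform spectrum."""
    B = np.full((4, 4), error_rate / 3.0)
    for t in range(4):
        B[t, 3 - t] = 1.0 - error_rate
    return B


@dataclass
class SimulationParams:
    """Full generative model for one synthetic experiment.

    Defaults correspond to the benchmark low-bias condition: 23% of primers
    extended, product lengths truncated-geometric with untruncated mean 3,
    uniform template composition, per-incorporated-base error 0.063 with a
    uniform mismatch spectrum, no ligation blocks.
    """

    n_reads: int = 10_000
    seed: int = 0
    template_len: int = 18
    template_composition: Optional[np.ndarray] = None  # (T, 4); None = uniform
    extension_prob: float = 0.23
    length_p: float = 1.0 / 3.0  # geometric success prob; mean 1/p before cap
    length_pmf: Optional[np.ndarray] = None  # over L = 1..T, overrides length_p
    base_bias: np.ndarray = field(default_factory=_default_base_bias)  # B(t, p)
    ligation_prob: float = 0.0
    ligation_len: int = 8
    ligation_error_rate: float = 0.25
    seq_error_rate: float = 0.001
    read_len: int = 70
    phred_q: int = 37

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        T = self.template_len
        if self.template_composition is not None:
            tc = np.asarray(self.template_composition, dtype=float)
            if tc.shape != (T, 4) or not np.allclose(tc.sum(axis=1), 1.0):
                raise ValueError("template_composition rows must be length-4 and sum to 1")
        B = np.asarray(self.base_bias, dtype=float)
        if B.shape != (4, 4) or not np.allclose(B.sum(axis=1), 1.0) or (B < 0).any():
            raise ValueError("base_bias rows must be stochastic")
        if not 0.0 <= self.extension_prob <= 1.0:
            raise ValueError("extension_prob must be in [0, 1]")
        if self.length_pmf is not None:
            pmf = np.asarray(self.length_pmf, dtype=float)
            if pmf.shape != (T,) or not np.isclose(pmf.sum(), 1.0) or (pmf < 0).any():
                raise ValueError("length_pmf must be a distribution over L = 1..T")
        elif not 0.0 < self.length_p <= 1.0:
            raise ValueError("length_p must be in (0, 1]")
        for name in ("ligation_prob", "ligation_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1 <= self.ligation_len <= T:
            raise ValueError("ligation_len must be in [1, template_len]")
        if not 0 <= self.phred_q <= 60:
            raise ValueError("phred_q must be in [0, 60]")

    def composition(self) -> np.ndarray:
        if self.template_composition is None:
            return np.full((self.template_len, 4), 0.25)
        return np.asarray(self.template_composition, dtype=float)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


@dataclass(frozen=True)
class TruthRecord:
    """One simulated molecule: its pair plus generative annotations."""

    pair: TemplateProductPair
    ligated: bool


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def simulate_pairs(
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> list[TruthRecord]:
    """Draw ``n_reads`` molecules from the generative model.

    Returns ground-truth records in templating order (template base t_1
    directs product position +1), before any sequencing error.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n, T = params.n_reads, params.template_len

    comp_cum = np.cumsum(params.composition(), axis=1)
    tpl = (rng.random((n, T))[:, :, None] > comp_cum[None, :, :]).sum(axis=2)
    tpl = tpl.astype(np.int8)

    extended = rng.random(n) < params.extension_prob
    if params.length_pmf is not None:
        cum = np.cumsum(np.asarray(params.length_pmf, dtype=float))
        lengths = 1 + (rng.random(n)[:, None] > cum[None, :]).sum(axis=1)
    else:
        lengths = np.minimum(rng.geometric(params.length_p, size=n), T)
    lengths = np.where(extended, lengths, 0).astype(np.int64)

    lig = extended & (rng.random(n) < params.ligation_prob)
    lig_start = lengths.copy()
    lengths = np.where(lig, np.minimum(lengths + params.ligation_len, T), lengths)

    B_cum = np.cumsum(np.asarray(params.base_bias, dtype=float), axis=1)
    u = rng.random((n, T))
    prod = (u[:, :, None] > B_cum[tpl]).sum(axis=2).astype(np.int8)

    Bblk = _default_base_bias(params.ligation_error_rate)
    u_blk = rng.random((n, T))
    prod_blk = (u_blk[:, :, None] > np.cumsum(Bblk, axis=1)[tpl]).sum(axis=2)
    pos = np.arange(T)[None, :]
    in_block = lig[:, None] & (pos >= lig_start[:, None]) & (pos < lengths[:, None])
    prod = np.where(in_block, prod_blk, prod).astype(np.int8)

    records = []
    for k in range(n):
        L = int(lengths[k])
        pair = TemplateProductPair.from_sequences(
            template=_codes_to_str(tpl[k]),
            product=_codes_to_str(prod[k, :L]) if L else "",
            source_id=f"mol{k:07d}",
        )
        records.append(TruthRecord(pair=pair, ligated=bool(lig[k])))
    return records


# ---------------------------------------------------------------------------
# Read rendering
# ---------------------------------------------------------------------------


def _apply_seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for i in positions:
        alternatives = [b for b in "ACGU" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _open_write(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def render_fastq(
    truth: Sequence[TruthRecord],
    spec: ConstructSpec,
    params: SimulationParams,
    r1_path: str | Path,
    r2_path: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Write paired FASTQ for a list of truth records.

    The forward read is the first ``read_len`` bases of the insert; the
    reverse read is the reverse complement of the last ``read_len`` bases.
    Reads are emitted in the DNA alphabet with constant Phred+33 quality;
    per-base substitution errors are applied to each mate independently.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    # mates must overlap by >= 10 nt even on the longest possible insert
    if 2 * params.read_len - spec.max_insert_len < 10:
        raise ValueError(
            "read_len too short for forward/reverse overlap on the longest insert"
        )
    qchar = chr(33 + params.phred_q)
    r1_path, r2_path = Path(r1_path), Path(r2_path)
    with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
        for rec in truth:
            insert = spec.assemble_insert(rec.pair.template, rec.pair.product)
            rl = min(params.read_len, len(insert))
            fwd = _apply_seq_errors(insert[:rl], params.seq_error_rate, rng)
            rev = _apply_seq_errors(
                reverse_complement(insert[-rl:]), params.seq_error_rate, rng
            )
            rid = rec.pair.source_id
            f1.write(f"@{rid}/1\n{fwd.translate(_RNA_TO_DNA)}\n+\n{qchar * rl}\n")
            f2.write(f"@{rid}/2\n{rev.translate(_RNA_TO_DNA)}\n+\n{qchar * rl}\n")


_TRUTH_HEADER = "id\ttemplate\tproduct\tlength\tcalls\tligated"


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for rec in truth:
            p = rec.pair
            fh.write(
                f"{p.source_id}\t{p.template}\t{p.product}\t{p.length}\t"
                f"{','.join(p.calls)}\t{int(rec.ligated)}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise ValueError(f"unexpected truth TSV header in {path}")
        for line in fh:
            pid, template, product, _L, _calls, lig = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    pair=TemplateProductPair.from_sequences(
                        template, product, source_id=pid
                    ),
                    ligated=bool(int(lig)),
                )
            )
    return records


def simulate_experiment(
    params: SimulationParams,
    spec: ConstructSpec,
    outdir: str | Path,
    gzipped: bool = False,
) -> dict:
    """Simulate an experiment plus its no-extension control into ``outdir``.

    Writes experiment and control R1/R2 FASTQ, truth TSVs for both, and a
    JSON echo of the parameters (seed included).  Returns the path map.
    """
    params.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzipped else ".fastq"

    ss = np.random.SeedSequence(params.seed)
    s_pairs, s_render, s_cpairs, s_crender = ss.spawn(4)

    truth = simulate_pairs(params, rng=np.random.default_rng(s_pairs))
    ctl_params = dataclasses.replace(params, extension_prob=0.0)
    ctl_truth = simulate_pairs(ctl_params, rng=np.random.default_rng(s_cpairs))

    paths = {
        "experiment_r1": outdir / f"experiment_R1{ext}",
        "experiment_r2": outdir / f"experiment_R2{ext}",
        "control_r1": outdir / f"control_R1{ext}",
        "control_r2": outdir / f"control_R2{ext}",
        "experiment_truth": outdir / "experiment_truth.tsv",
        "control_truth": outdir / "control_truth.tsv",
        "params": outdir / "params.json",
    }
    render_fastq(
        truth, spec, params, paths["experiment_r1"], paths["experiment_r2"],
        rng=np.random.default_rng(s_render),
    )
    render_fastq(
        ctl_truth, spec, ctl_params, paths["control_r1"], paths["control_r2"],
        rng=np.random.default_rng(s_crender),
    )
    write_truth_tsv(truth, paths["experiment_truth"])
    write_truth_tsv(ctl_truth, paths["control_truth"])
    paths["params"].write_text(
        json.dumps({"construct": spec.to_dict(), "params": params.to_jsonable()},
                   indent=2, sort_keys=True) + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
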