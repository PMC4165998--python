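"""Monte-Carlo characterization of the VAF estimator, plus a read-level
fixture alignment generator for end-to-end tests.

Two levels of simulation are provided:

* **count-level** — evidence counts are drawn directly from the model's
  Poisson channels (binomial for the SNV comparator) and fed back to the
  maximum-likelihood estimator. This is what the accuracy grids and the
  clone-mixture error study use.
* **read-level** — :func:`generate_fixture_bam` writes a small sorted,
  indexed BAM with planted SVs (proper pairs for the reference allele;
  enlarged-insert pairs and clipped reads for deletions, everted pairs for
  tandem duplications, same-strand pairs for inversions, cross-contig pairs
  for translocations) so the evidence-extraction code can be exercised
  without external data.

Accuracy is scored as the chance of the estimate landing within a
*relative* 10% band of the truth, |p_hat - p| <= tol * p; at p = 0 the band
degenerates to exact recovery of 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import NOISE_FLOOR_EPS, _mle_arrays
from .types import BinCount, GCRateTable, LibraryParams, ObservedCounts, SVCall

VARIANT_KINDS = ("SNV", "DEL", "DUP", "INV_or_TRA")


# ---------------------------------------------------------------------------
# Count-level scenarios
# ---------------------------------------------------------------------------


@dataclass
class SimScenario:
    """One cell of the accuracy characterization grid.

    ``coverage`` is fold sequence coverage; the implied pair rate is
    c = coverage / (2 * read_length) pairs per bp. Depth bins apply to
    deletions/duplications only; an inversion or reciprocal translocation
    has two junctions simulated independently and no depth channel.
    """

    variant_kind: str
    true_p: float
    coverage: float
    read_length: int = 100
    insert_size: int = 500
    sv_size: int = 1_000_000
    bin_width: int = 100
    n_trials: int = 1000
    tolerance: float = 0.10
    seed: Optional[int] = None
    offset_vd: float = 0.8
    offset_vs: float = 0.7

    def __post_init__(self):
        if self.variant_kind not in VARIANT_KINDS:
            raise ValueError(f"variant_kind must be one of {VARIANT_KINDS}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.true_p <= 1.0:
            raise ValueError("true_p must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def pairs_per_bp(self) -> float:
        return self.coverage / (2.0 * self.read_length)

    def library_params(self) -> LibraryParams:
        return LibraryParams(
            library_id="sim",
            read_length_r=self.read_length,
            insert_median_t=self.insert_size,
            insert_spread=0.1 * self.insert_size,
            inserts_per_bp_c=self.pairs_per_bp,
            offset_vd=self.offset_vd,
            offset_vs=self.offset_vs,
        )


def _scenario_channels(sc: SimScenario):
    """Affine channel coefficients (alpha, beta) in canonical order
    (depth bins, then d/s per junction) for a non-SNV scenario."""
    c = sc.pairs_per_bp
    alphas, betas = [], []
    widths = []
    if sc.variant_kind in ("DEL", "DUP"):
        n_full, rem = divmod(sc.sv_size, sc.bin_width)
        widths = [sc.bin_width] * n_full + ([rem] if rem else [])
        sign = -1.0 if sc.variant_kind == "DEL" else 1.0
        for w in widths:
            a = c * w
            alphas.append(a)
            betas.append(sign * a)
    n_junc = 2 if sc.variant_kind == "INV_or_TRA" else 1
    span = sc.insert_size - 2 * sc.read_length
    beta_d = sc.offset_vd * c * max(span, 0.0)
    beta_s = sc.offset_vs * c * 2 * sc.read_length
    for _ in range(n_junc):
        alphas.extend((0.0, 0.0))
        betas.extend((beta_d, beta_s))
    return np.array(alphas), np.array(betas), widths


def _simulate_flat(sc: SimScenario, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` trials of the flat count vector, shape (n, nchan)."""
    alpha, beta, _ = _scenario_channels(sc)
    lam = np.maximum(alpha + beta * sc.true_p, 0.0)
    return rng.poisson(lam, size=(n, lam.size))


def simulate_counts(sc: SimScenario, rng: np.random.Generator):
    """Simulate one trial of evidence counts under the scenario's rates.

    For SNVs returns ``(variant_reads, total_reads)`` with variant reads
    binomial at depth round(coverage); otherwise returns an
    :class:`ObservedCounts` with per-bin Poisson normal-pair counts (CNVs)
    and Poisson junction counts.
    """
    if sc.variant_kind == "SNV":
        total = int(round(sc.coverage))
        return int(rng.binomial(total, sc.true_p)), total
    alpha, beta, widths = _scenario_channels(sc)
    draw = _simulate_flat(sc, rng, 1)[0]
    m = len(widths)
    bins = [
        BinCount(gc_theta=50, width=w, n_i=int(v))
        for w, v in zip(widths, draw[:m])
    ]
    junctions = [
        (int(draw[m + 2 * j]), int(draw[m + 2 * j + 1]))
        for j in range((len(draw) - m) // 2)
    ]
    return ObservedCounts(bins=bins, junctions=junctions, library_id="sim")


def estimate_scenario_vafs(
    sc: SimScenario,
    rng: Optional[np.random.Generator] = None,
    *,
    noise_floor_eps: float = NOISE_FLOOR_EPS,
) -> np.ndarray:
    """Run ``n_trials`` simulate-then-estimate cycles; returns the p_hat array.

    SNVs use the plain binomial fraction k/n as the estimator; SVs use the
    closed-form Poisson MLE over their channels.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    if sc.variant_kind == "SNV":
        total = int(round(sc.coverage))
        k = rng.binomial(total, sc.true_p, size=sc.n_trials)
        return k / total
    alpha, beta, _ = _scenario_channels(sc)
    draws = _simulate_flat(sc, rng, sc.n_trials)
    return np.array(
        [_mle_arrays(alpha, beta, d.astype(float), noise_floor_eps) for d in draws]
    )


def accuracy_of(p_hats: np.ndarray, true_p: float, tolerance: float) -> float:
    """Fraction of estimates within the relative tolerance band of truth."""
    p_hats = np.asarray(p_hats, dtype=float)
    if true_p == 0.0:
        return float(np.mean(p_hats == 0.0))
    return float(np.mean(np.abs(p_hats - true_p) <= tolerance * true_p))


def accuracy_curve(scenarios: Iterable[SimScenario]) -> pd.DataFrame:
    """Accuracy table over a grid of scenarios.

    One row per scenario: variant kind, condition (coverage/insert/size),
    true VAF and the fraction of trials whose estimate fell within the
    relative tolerance band.
    """
    rows = []
    for sc in scenarios:
        p_hats = estimate_scenario_vafs(sc)
        rows.append(
            {
                "variant_kind": sc.variant_kind,
                "coverage": sc.coverage,
                "insert_size": sc.insert_size,
                "sv_size": sc.sv_size if sc.variant_kind in ("DEL", "DUP") else np.nan,
                "true_p": sc.true_p,
                "n_trials": sc.n_trials,
                "tolerance": sc.tolerance,
                "accuracy": accuracy_of(p_hats, sc.true_p, sc.tolerance),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clone-mixture error study
# ---------------------------------------------------------------------------

#: clone mass fractions of the mock 5-clone tumor (sum to 1 at zero
#: contamination) and, per SV, the set of clones carrying it. Carrier-set
#: sums are chosen so the 10 heterozygous single-copy SVs have true VAFs
#: {0.05, 0.075, ..., 0.25, 0.3} in the uncontaminated sample.
DEFAULT_CLONE_FRACTIONS = (0.05, 0.10, 0.15, 0.30, 0.40)
DEFAULT_SV_CARRIERS = (
    (1,),  # 0.10 -> VAF 0.050
    (2,),  # 0.15 -> VAF 0.075
    (0, 2),  # 0.20 -> VAF 0.100
    (1, 2),  # 0.25 -> VAF 0.125
    (3,),  # 0.30 -> VAF 0.150
    (0, 3),  # 0.35 -> VAF 0.175
    (4,),  # 0.40 -> VAF 0.200
    (0, 4),  # 0.45 -> VAF 0.225
    (1, 4),  # 0.50 -> VAF 0.250
    (0, 2, 4),  # 0.60 -> VAF 0.300
)
DEFAULT_SV_KINDS = ("DEL", "DUP") * 5


@dataclass
class CloneMixSpec:
    """A polyclonal tumor mixed with normal cells.

    Each SV is a heterozygous single-copy event (deletion or one-copy tandem
    duplication) of ``sv_size`` bp carried by a subset of clones; its true
    VAF is (sum of carrying-clone fractions) * (1 - contamination) / 2.
    """

    clone_fractions: Sequence[float] = DEFAULT_CLONE_FRACTIONS
    sv_carriers: Sequence[tuple] = DEFAULT_SV_CARRIERS
    sv_kinds: Sequence[str] = DEFAULT_SV_KINDS
    contamination: float = 0.0
    total_coverage: float = 50.0
    sv_size: int = 1_500_000
    read_length: int = 100
    insert_size: int = 500
    bin_width: int = 100

    def __post_init__(self):
        f = np.asarray(self.clone_fractions, dtype=float)
        if np.any(f < 0):
            raise ValueError("clone fractions must be non-negative")
        if f.sum() > 1.0 + 1e-9:
            raise ValueError("clone fractions exceed 1")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must lie in [0, 1]")
        if len(self.sv_carriers) != len(self.sv_kinds):
            raise ValueError("one kind per SV required")

    def true_vafs(self) -> np.ndarray:
        f = np.asarray(self.clone_fractions, dtype=float)
        sums = np.array([f[list(c)].sum() for c in self.sv_carriers])
        return sums * (1.0 - self.contamination) / 2.0


def clone_mixture_errors(spec: CloneMixSpec, rng: np.random.Generator):
    """Simulate each SV's evidence at its diluted true VAF and re-estimate.

    Returns ``(mean_abs_error, max_abs_error, table)`` over the SVs, where
    the table lists per-SV truth, estimate and absolute error.
    """
    rows = []
    for i, (p_true, kind) in enumerate(zip(spec.true_vafs(), spec.sv_kinds)):
        sc = SimScenario(
            variant_kind=kind,
            true_p=float(p_true),
            coverage=spec.total_coverage,
            read_length=spec.read_length,
            insert_size=spec.insert_size,
            sv_size=spec.sv_size,
            bin_width=spec.bin_width,
            n_trials=1,
        )
        alpha, beta, _ = _scenario_channels(sc)
        draw = _simulate_flat(sc, rng, 1)[0].astype(float)
        p_hat = _mle_arrays(alpha, beta, draw, NOISE_FLOOR_EPS)
        rows.append(
            {
                "sv": i,
                "kind": kind,
                "contamination": spec.contamination,
                "true_vaf": float(p_true),
                "est_vaf": p_hat,
                "abs_error": abs(p_hat - p_true),
            }
        )
    table = pd.DataFrame(rows)
    return float(table["abs_error"].mean()), float(table["abs_error"].max()), table


# ---------------------------------------------------------------------------
# Read-level fixture generator
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


class _ReadBuffer:
    """Collects mate-paired alignment records before sorting into a BAM."""

    def __init__(self, header):
        import pysam

        self.header = pysam.AlignmentHeader.from_dict(header)
        self.records = []
        self._serial = 0

    def add_pair(
        self,
        name_prefix: str,
        first: dict,
        second: dict,
        proper: bool = False,
    ):
        import pysam

        self._serial += 1
        name = f"{name_prefix}_{self._serial}"
        recs = []
        for me, other, is_first in ((first, second, True), (second, first, False)):
            a = pysam.AlignedSegment(self.header)
            a.query_name = name
            a.query_sequence = me["seq"]
            a.reference_id = self.header.get_tid(me["chrom"])
            a.reference_start = me["pos"]
            a.cigarstring = me["cigar"]
            a.mapping_quality = me.get("mapq", 60)
            a.flag = (
                0x1
                | (0x2 if proper else 0)
                | (0x10 if me["reverse"] else 0)
                | (0x20 if other["reverse"] else 0)
                | (0x40 if is_first else 0x80)
            )
            a.next_reference_id = self.header.get_tid(other["chrom"])
            a.next_reference_start = other["pos"]
            if me["chrom"] == other["chrom"]:
                lo = min(me["pos"], other["pos"])
                hi = max(me["pos"] + len(me["seq"]), other["pos"] + len(other["seq"]))
                a.template_length = (hi - lo) if me["pos"] <= other["pos"] else -(hi - lo)
            else:
                a.template_length = 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(me["seq"]))
            recs.append(a)
        self.records.extend(recs)

    def write(self, path: str):
        import pysam

        self.records.sort(key=lambda a: (a.reference_id, a.reference_start))
        tmp = path + ".unsorted.bam"
        with pysam.AlignmentFile(tmp, "wb", header=self.header) as fh:
            for a in self.records:
                fh.write(a)
        pysam.sort("-o", path, tmp)
        os.remove(tmp)
        pysam.index(path)


def generate_fixture_bam(
    genome_length: int,
    svs: Sequence[tuple],
    params: LibraryParams,
    coverage: float,
    seed: int,
    out_prefix: str,
    *,
    gc_bias: Optional[Callable[[float], float]] = None,
    reference_seqs: Optional[dict] = None,
) -> dict:
    """Write a sorted, indexed BAM with planted SVs and the matching truth.

    ``svs`` is a list of ``(SVCall, true_p)``; intra-chromosomal events must
    not overlap. The reference is a random sequence (contig ``chr1``, plus
    ``chr2`` when a translocation needs it) unless ``reference_seqs``
    supplies explicit sequences. Proper pairs are laid down genome-wide at
    the pair rate c = coverage/(2r); inside a deletion they are thinned by
    the allele fraction p and inside a duplication boosted by p. Junction
    evidence is planted at the model rates v_d*c*(t-2r)*p (discordant pairs,
    with type-specific geometry) and v_s*c*2r*p (soft-clipped reads whose
    clip coordinate sits on the breakpoint). ``gc_bias`` optionally thins
    proper pairs by a factor of the local GC fraction to emulate GC bias.

    Returns a dict with the written paths (``bam``, ``fasta``, ``truth``)
    and the truth table (one row per SV).
    """
    import pysam

    rng = np.random.default_rng(seed)
    r = int(params.read_length_r)
    t = int(params.insert_median_t)
    c = coverage / (2.0 * r)

    for i, (sv, p) in enumerate(svs):
        if not 0.0 <= p <= 1.0:
            raise ValueError("true_p must lie in [0, 1]")
        for sv2, _ in svs[i + 1 :]:
            if sv.chrom1 == sv2.chrom1 and sv.sv_type != "TRA" and sv2.sv_type != "TRA":
                if sv.pos1 < sv2.pos2 and sv2.pos1 < sv.pos2:
                    raise ValueError(f"overlapping SVs: {sv} / {sv2}")

    contigs = {"chr1": genome_length}
    for sv, _ in svs:
        for ch in (sv.chrom1, sv.chrom2):
            contigs.setdefault(ch, genome_length)
    if reference_seqs is None:
        reference_seqs = {
            name: _random_sequence(rng, length) for name, length in contigs.items()
        }
    else:
        contigs = {name: len(s) for name, s in reference_seqs.items()}

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    buf = _ReadBuffer(header)

    def read_seq(chrom, start, length, reverse=False):
        s = reference_seqs[chrom][start : start + length]
        return _revcomp(s) if reverse else s

    # --- reference-allele proper pairs (with DEL thinning / DUP boost) ---
    del_regions = {
        (sv.chrom1, sv.pos1 - 1, sv.pos2 - 1): p
        for sv, p in svs
        if sv.sv_type == "DEL"
    }
    dup_regions = {
        (sv.chrom1, sv.pos1 - 1, sv.pos2 - 1): p
        for sv, p in svs
        if sv.sv_type == "DUP"
    }
    for chrom, length in contigs.items():
        n_pairs = rng.poisson(c * length)
        starts = rng.integers(0, max(1, length - t), size=n_pairs)
        inserts = np.maximum(
            2 * r,
            rng.normal(t, params.insert_spread, size=n_pairs).round().astype(int),
        )
        for start, ins in zip(starts, inserts):
            start = int(start)
            ins = int(min(ins, length - start))
            if ins < 2 * r:
                continue
            keep = 1.0
            for (ch, lo, hi), p in del_regions.items():
                if ch == chrom and lo <= start < hi:
                    keep *= 1.0 - p
            if gc_bias is not None:
                # thin by the GC of the 100 bp at the pair start — the same
                # leftmost-base convention used when counting pairs into bins
                keep *= gc_bias(_gc_fraction(reference_seqs[chrom][start : start + 100]))
            if rng.random() > keep:
                continue
            buf.add_pair(
                "ref",
                {
                    "chrom": chrom,
                    "pos": start,
                    "seq": read_seq(chrom, start, r),
                    "cigar": f"{r}M",
                    "reverse": False,
                },
                {
                    "chrom": chrom,
                    "pos": start + ins - r,
                    "seq": read_seq(chrom, start + ins - r, r, reverse=True),
                    "cigar": f"{r}M",
                    "reverse": True,
                },
                proper=True,
            )
        # duplication allele adds extra proper pairs inside the duplicated copy
        for (ch, lo, hi), p in dup_regions.items():
            if ch != chrom:
                continue
            n_extra = rng.poisson(c * p * (hi - lo))
            for start in rng.integers(lo, hi, size=n_extra):
                start = int(start)
                ins = int(
                    max(2 * r, round(rng.normal(t, params.insert_spread)))
                )
                ins = min(ins, length - start)
                if ins < 2 * r:
                    continue
                buf.add_pair(
                    "dupcov",
                    {
                        "chrom": chrom,
                        "pos": start,
                        "seq": read_seq(chrom, start, r),
                        "cigar": f"{r}M",
                        "reverse": False,
                    },
                    {
                        "chrom": chrom,
                        "pos": start + ins - r,
                        "seq": read_seq(chrom, start + ins - r, r, reverse=True),
                        "cigar": f"{r}M",
                        "reverse": True,
                    },
                    proper=True,
                )

    # --- variant-allele junction evidence ---
    span = max(t - 2 * r, 1)
    for sv, p in svs:
        n_drp = rng.poisson(params.offset_vd * c * span * p * sv.n_junctions)
        n_sr = rng.poisson(params.offset_vs * c * 2 * r * p * sv.n_junctions)
        for j in range(n_drp):
            _plant_drp(buf, sv, rng, r, t, read_seq)
        for j in range(n_sr):
            _plant_softclip(buf, sv, rng, r, t, read_seq)

    bam_path = out_prefix + ".bam"
    fa_path = out_prefix + ".fa"
    truth_path = out_prefix + ".truth.tsv"
    buf.write(bam_path)
    with open(fa_path, "w") as fh:
        for name, s in reference_seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    pysam.faidx(fa_path)
    truth = pd.DataFrame(
        [
            {
                "chrom1": sv.chrom1,
                "pos1": sv.pos1,
                "chrom2": sv.chrom2,
                "pos2": sv.pos2,
                "sv_type": sv.sv_type,
                "size": sv.size if sv.size is not None else -1,
                "true_p": p,
            }
            for sv, p in svs
        ]
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"bam": bam_path, "fasta": fa_path, "truth_path": truth_path, "truth": truth}


def _plant_drp(buf, sv: SVCall, rng, r: int, t: int, read_seq):
    """One discordant pair with the junction geometry of sv's type.

    Offsets mimic a fragment of length t spanning the junction with both
    reads clear of the breakpoint (offset u ~ Uniform(r, t-r) along the
    fragment), so apparent insert anomalies match what an aligner reports.
    """
    u = int(rng.integers(r, t - r + 1))  # junction offset within the fragment
    p1, p2 = sv.pos1 - 1, sv.pos2 - 1  # 0-based breakpoints
    if sv.sv_type == "DEL":
        left_start = p1 - u
        right_start = p2 + (t - u) - r
        buf.add_pair(
            "drp",
            {"chrom": sv.chrom1, "pos": left_start, "seq": read_seq(sv.chrom1, left_start, r), "cigar": f"{r}M", "reverse": False},
            {"chrom": sv.chrom1, "pos": right_start, "seq": read_seq(sv.chrom1, right_start, r, True), "cigar": f"{r}M", "reverse": True},
        )
    elif sv.sv_type == "DUP":
        # tandem junction (end|start): everted pair, leftmost read reverse
        fwd_start = p2 - u  # forward read just left of the dup end
        rev_start = p1 + (t - u) - r  # reverse read just right of the dup start
        buf.add_pair(
            "drp",
            {"chrom": sv.chrom1, "pos": fwd_start, "seq": read_seq(sv.chrom1, fwd_start, r), "cigar": f"{r}M", "reverse": False},
            {"chrom": sv.chrom1, "pos": rev_start, "seq": read_seq(sv.chrom1, rev_start, r, True), "cigar": f"{r}M", "reverse": True},
        )
    elif sv.sv_type == "INV":
        # an inverted segment flips the strand of reads mapping inside it
        if rng.random() < 0.5:  # fragment across the left junction: FF pair
            a = p1 - u  # forward, left of pos1
            b = p2 - (t - u)  # mate maps near pos2, flipped to forward
            buf.add_pair(
                "drp",
                {"chrom": sv.chrom1, "pos": a, "seq": read_seq(sv.chrom1, a, r), "cigar": f"{r}M", "reverse": False},
                {"chrom": sv.chrom1, "pos": b, "seq": read_seq(sv.chrom1, b, r), "cigar": f"{r}M", "reverse": False},
            )
        else:  # fragment across the right junction: RR pair
            a = p1 + u - r  # inside the inversion, flipped to reverse
            b = p2 + (t - u) - r  # reverse, right of pos2
            buf.add_pair(
                "drp",
                {"chrom": sv.chrom1, "pos": a, "seq": read_seq(sv.chrom1, a, r, True), "cigar": f"{r}M", "reverse": True},
                {"chrom": sv.chrom1, "pos": b, "seq": read_seq(sv.chrom1, b, r, True), "cigar": f"{r}M", "reverse": True},
            )
    else:  # TRA: reciprocal fusion, mates on the two partner contigs
        if rng.random() < 0.5:  # derivative 1: chr1[..pos1] joined to chr2[pos2..]
            a = p1 - u
            b = p2 + (t - u) - r
            buf.add_pair(
                "drp",
                {"chrom": sv.chrom1, "pos": a, "seq": read_seq(sv.chrom1, a, r), "cigar": f"{r}M", "reverse": False},
                {"chrom": sv.chrom2, "pos": b, "seq": read_seq(sv.chrom2, b, r, True), "cigar": f"{r}M", "reverse": True},
            )
        else:  # derivative 2: chr2[..pos2] joined to chr1[pos1..]
            a = p2 - u
            b = p1 + (t - u) - r
            buf.add_pair(
                "drp",
                {"chrom": sv.chrom2, "pos": a, "seq": read_seq(sv.chrom2, a, r), "cigar": f"{r}M", "reverse": False},
                {"chrom": sv.chrom1, "pos": b, "seq": read_seq(sv.chrom1, b, r, True), "cigar": f"{r}M", "reverse": True},
            )


def _plant_softclip(buf, sv: SVCall, rng, r: int, t: int, read_seq):
    """One read whose clip coordinate sits on a breakpoint of sv.

    At the left-side breakpoint the matched prefix ends on the breakpoint
    and the tail is clipped; at the right-side breakpoint the matched
    suffix starts on the breakpoint and the head is clipped. Clipped bases
    are random (they belong to the other side of the junction). The mate is
    an ordinary fully aligned read at roughly insert distance so the pair's
    flags stay coherent.
    """
    m = int(rng.integers(max(10, r // 4), r - 10 + 1))  # matched length
    clip = r - m
    left_side = rng.random() < 0.5
    if left_side:
        chrom, bp0 = sv.chrom1, sv.pos1 - 1
    else:
        chrom = sv.chrom2 if sv.sv_type == "TRA" else sv.chrom1
        bp0 = sv.pos2 - 1
    if left_side:
        start = bp0 - m
        seq = read_seq(chrom, start, m) + _random_sequence(rng, clip)
        cigar = f"{m}M{clip}S"
    else:
        start = bp0
        seq = _random_sequence(rng, clip) + read_seq(chrom, start, m)
        cigar = f"{clip}S{m}M"
    mate_start = start + t - r  # FR mate downstream at about insert distance
    buf.add_pair(
        "clip",
        {"chrom": chrom, "pos": start, "seq": seq, "cigar": cigar, "reverse": False},
        {"chrom": chrom, "pos": mate_start, "seq": read_seq(chrom, mate_start, r, True), "cigar": f"{r}M", "reverse": True},
    )
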