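"""Evidence extraction: classify read pairs around a candidate SV and
count them into the three model channels.

A read pair overlapping the evidence region is assigned to exactly one of

* ``NORMAL``     — expected orientation (FR) with insert within
                   median +/- k * spread; counted into GC-annotated depth
                   bins by the leftmost aligned base of the left mate,
* ``DISCORDANT`` — anomalous contigs/orientation/insert *and* geometrically
                   consistent with the candidate SV's junction(s),
* ``SOFTCLIP``   — carries a clip of >= min_clip bases whose clip
                   coordinate falls within +/- clip_slop of a predicted
                   breakpoint (takes priority over pair-level classes:
                   the clip is the more specific signal),
* ``EXCLUDED``   — duplicates, secondary/supplementary, QC-fail, unmapped
                   mates, or anomalies not attributable to this SV.

Depth bins tile the deleted/duplicated interval; balanced SVs (INV, TRA)
carry no depth signal and instead contribute two junction windows of
half-width t + k * spread around each breakpoint.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

import numpy as np

from .types import BinCount, GCRateTable, LibraryParams, ObservedCounts, SVCall

DEFAULT_BIN_WIDTH = 100
DEFAULT_K = 3.0
DEFAULT_MIN_CLIP = 5
DEFAULT_CLIP_SLOP = 5
DEFAULT_MQ0_THRESHOLD = 0.5


class ReadClass(Enum):
    NORMAL = "NORMAL"
    DISCORDANT = "DISCORDANT"
    SOFTCLIP = "SOFTCLIP"
    EXCLUDED = "EXCLUDED"


def _clip_coords(read):
    """(reference coordinate, clip length) of each soft clip on ``read``.

    A leading clip sits at ``reference_start``; a trailing clip at
    ``reference_end`` (0-based, exclusive end = first clipped base).
    """
    cig = read.cigartuples
    if not cig:
        return []
    out = []
    if cig[0][0] == 4:  # leading S
        out.append((read.reference_start, cig[0][1]))
    if cig[-1][0] == 4:  # trailing S
        out.append((read.reference_end, cig[-1][1]))
    return out


def _breakpoints(sv: SVCall):
    """Predicted breakpoints as (contig, 0-based coordinate)."""
    return [(sv.chrom1, sv.pos1 - 1), (sv.chrom2, sv.pos2 - 1)]


def _is_excluded(read) -> bool:
    return (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
        or not read.is_paired
        or read.mate_is_unmapped
    )


def _matches_breakpoint(read, sv: SVCall, min_clip: int, clip_slop: int) -> bool:
    ref = read.reference_name
    for coord, length in _clip_coords(read):
        if length < min_clip:
            continue
        for chrom, bp in _breakpoints(sv):
            if ref == chrom and abs(coord - bp) <= clip_slop:
                return True
    return False


def classify_read_pair(
    read,
    params: LibraryParams,
    sv: SVCall,
    *,
    k: float = DEFAULT_K,
    min_clip: int = DEFAULT_MIN_CLIP,
    clip_slop: int = DEFAULT_CLIP_SLOP,
) -> ReadClass:
    """Classify one primary alignment record (using its mate fields).

    The soft-clip test runs first: a breakpoint-matching clip is the most
    specific signal and claims the read regardless of pair geometry. Pair
    anomalies (wrong contig, orientation, or insert length) only count as
    DISCORDANT when their geometry matches the candidate SV's type;
    unexplained anomalies fall to EXCLUDED so they cannot inflate the
    evidence for *this* variant.
    """
    if _is_excluded(read):
        return ReadClass.EXCLUDED
    if _matches_breakpoint(read, sv, min_clip, clip_slop):
        return ReadClass.SOFTCLIP

    t, spread = params.insert_median_t, params.insert_spread
    lo, hi = t - k * spread, t + k * spread
    win = t + k * spread
    same_contig = read.reference_id == read.next_reference_id

    if not same_contig:
        if sv.sv_type == "TRA":
            pair = {read.reference_name, read.next_reference_name}
            if pair == {sv.chrom1, sv.chrom2}:
                # both ends near their breakpoints?
                here = read.reference_start
                there = read.next_reference_start
                bp_here = sv.pos1 - 1 if read.reference_name == sv.chrom1 else sv.pos2 - 1
                bp_there = (
                    sv.pos1 - 1 if read.next_reference_name == sv.chrom1 else sv.pos2 - 1
                )
                if abs(here - bp_here) <= win and abs(there - bp_there) <= win:
                    return ReadClass.DISCORDANT
        return ReadClass.EXCLUDED

    # same contig: orientation of (leftmost, rightmost) reads
    left_is_self = read.reference_start < read.next_reference_start or (
        read.reference_start == read.next_reference_start and read.is_read1
    )
    left_rev = read.is_reverse if left_is_self else read.mate_is_reverse
    right_rev = read.mate_is_reverse if left_is_self else read.is_reverse
    tlen = abs(read.template_length)

    fr = (not left_rev) and right_rev
    if fr and lo <= tlen <= hi:
        return ReadClass.NORMAL

    left_start = min(read.reference_start, read.next_reference_start)
    if sv.sv_type == "DEL":
        # enlarged apparent insert spanning both breakpoints
        if fr and tlen > hi and left_start <= sv.pos1 - 1 and left_start + tlen >= sv.pos2 - 1:
            return ReadClass.DISCORDANT
    elif sv.sv_type == "DUP":
        # everted (RF) pair inside the duplicated interval
        everted = left_rev and not right_rev
        if everted and sv.pos1 - 1 - win <= left_start <= sv.pos2 - 1 + win:
            return ReadClass.DISCORDANT
    elif sv.sv_type == "INV":
        # same-strand pair with ends near the two breakpoints
        if left_rev == right_rev:
            p1, p2 = sv.pos1 - 1, sv.pos2 - 1
            near = lambda x: min(abs(x - p1), abs(x - p2)) <= win
            if near(read.reference_start) and near(read.next_reference_start):
                return ReadClass.DISCORDANT
    return ReadClass.EXCLUDED


def filter_bins(bins, mq0_threshold: float = DEFAULT_MQ0_THRESHOLD):
    """Drop depth bins dominated by mapping-quality-zero reads.

    Bins whose MQ0 fraction exceeds the threshold sit in repetitive or
    otherwise unmappable sequence; their depth is unreliable. Order is
    preserved; the result may be empty.
    """
    return [b for b in bins if b.mq0_fraction <= mq0_threshold]


def _junction_index(read, sv: SVCall, clipped: bool, min_clip: int, clip_slop: int) -> int:
    """Which junction of a balanced SV a DRP/SR record belongs to.

    INV: forward-forward pairs span the left junction, reverse-reverse the
    right. TRA: the derivative with chrom1 read forward is junction 0, the
    reciprocal junction 1. Clipped reads go to the breakpoint nearest their
    clip coordinate.
    """
    if not sv.is_balanced:
        return 0  # DEL/DUP: both breakpoints feed the single junction
    if clipped:
        best, best_d = 0, None
        for coord, length in _clip_coords(read):
            if length < min_clip:
                continue
            for j, (chrom, bp) in enumerate(_breakpoints(sv)):
                if read.reference_name != chrom:
                    continue
                d = abs(coord - bp)
                if d <= clip_slop and (best_d is None or d < best_d):
                    best, best_d = j, d
        return best
    if sv.sv_type == "INV":
        return 0 if not read.is_reverse else 1
    if sv.sv_type == "TRA":
        fwd_on_1 = (read.reference_name == sv.chrom1 and not read.is_reverse) or (
            read.next_reference_name == sv.chrom1 and not read.mate_is_reverse
        )
        return 0 if fwd_on_1 else 1
    return 0


def count_evidence(
    alignment,
    sv: SVCall,
    params: LibraryParams,
    gc: GCRateTable,
    bin_width: int = DEFAULT_BIN_WIDTH,
    *,
    reference=None,
    k: float = DEFAULT_K,
    min_clip: int = DEFAULT_MIN_CLIP,
    clip_slop: int = DEFAULT_CLIP_SLOP,
    junction_halfwidth: Optional[int] = None,
) -> ObservedCounts:
    """Count the evidence D = {n_i, d, s} for one SV from an indexed BAM.

    For DEL/DUP the interval [pos1, pos2) is tiled into non-overlapping
    ``bin_width`` bins (last bin may be shorter); NORMAL pairs are assigned
    to bins by the leftmost aligned base of the left mate — the same
    convention used when calibrating the GC rate table, so rates cancel.
    Each bin is annotated with its GC percent (from ``reference`` when
    given, else from aligned read bases) and MQ0 fraction. Junction
    evidence (d, s) is collected from windows of half-width t + k*spread
    around each breakpoint; balanced SVs return two junctions and no bins.

    ``alignment`` is a ``pysam.AlignmentFile`` or a path; ``reference`` a
    ``pysam.FastaFile`` or FASTA path.
    """
    import pysam

    own_aln = isinstance(alignment, str)
    aln = pysam.AlignmentFile(alignment) if own_aln else alignment
    own_ref = isinstance(reference, str)
    ref = pysam.FastaFile(reference) if own_ref else reference
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    halfw = (
        int(params.insert_median_t + k * params.insert_spread)
        if junction_halfwidth is None
        else junction_halfwidth
    )

    try:
        contig_len = dict(zip(aln.references, aln.lengths))
        for chrom, bp in _breakpoints(sv):
            if chrom not in contig_len or not 0 <= bp < contig_len[chrom]:
                raise ValueError(f"breakpoint {chrom}:{bp + 1} outside contig bounds")

        # --- junction windows: discordant pairs and soft-clipped reads ---
        n_junc = sv.n_junctions
        d_counts = [0] * n_junc
        s_counts = [0] * n_junc
        seen_drp: set = set()
        seen_sr: set = set()
        sr_names: set = set()
        windows = []
        for chrom, bp in _breakpoints(sv):
            lo = max(0, bp - halfw)
            hi = min(contig_len[chrom], bp + halfw + 1)
            windows.append((chrom, lo, hi))
        for chrom, lo, hi in windows:
            for read in aln.fetch(chrom, lo, hi):
                cls = classify_read_pair(
                    read, params, sv, k=k, min_clip=min_clip, clip_slop=clip_slop
                )
                if cls == ReadClass.SOFTCLIP:
                    key = (read.query_name, read.is_read1)
                    if key not in seen_sr:
                        seen_sr.add(key)
                        sr_names.add(read.query_name)
                        s_counts[_junction_index(read, sv, True, min_clip, clip_slop)] += 1
                elif cls == ReadClass.DISCORDANT:
                    if read.query_name not in seen_drp:
                        seen_drp.add(read.query_name)
                        d_counts[_junction_index(read, sv, False, min_clip, clip_slop)] += 1

        junction_gc = None
        if ref is not None:
            junction_gc = []
            bps = _breakpoints(sv) if n_junc == 2 else [_breakpoints(sv)[0]]
            for chrom, bp in bps:
                seq = ref.fetch(chrom, max(0, bp - halfw), bp + halfw).upper()
                junction_gc.append(_gc_percent(seq))

        # --- depth bins (unbalanced SVs only) ---
        bins: list[BinCount] = []
        if not sv.is_balanced:
            start0, end0 = sv.pos1 - 1, sv.pos2 - 1
            edges = list(range(start0, end0, bin_width)) + [end0]
            m = len(edges) - 1
            n_arr = np.zeros(m, dtype=int)
            reads_in_bin = np.zeros(m, dtype=int)
            mq0_in_bin = np.zeros(m, dtype=int)
            gc_bases = np.zeros(m, dtype=float)
            tot_bases = np.zeros(m, dtype=float)
            for read in aln.fetch(sv.chrom1, start0, end0):
                if _is_excluded(read):
                    continue
                pos = read.reference_start
                if not start0 <= pos < end0:
                    continue
                b = min((pos - start0) // bin_width, m - 1)
                reads_in_bin[b] += 1
                if read.mapping_quality == 0:
                    mq0_in_bin[b] += 1
                if ref is None:
                    seq = read.query_alignment_sequence or ""
                    gc_bases[b] += seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
                    tot_bases[b] += len(seq)
                cls = classify_read_pair(
                    read, params, sv, k=k, min_clip=min_clip, clip_slop=clip_slop
                )
                if cls != ReadClass.NORMAL:
                    continue
                if read.query_name in sr_names:
                    continue  # pair already claimed by the soft-clip channel
                left_is_self = pos < read.next_reference_start or (
                    pos == read.next_reference_start and read.is_read1
                )
                if left_is_self:
                    n_arr[b] += 1
            for b in range(m):
                width = edges[b + 1] - edges[b]
                if ref is not None:
                    seq = ref.fetch(sv.chrom1, edges[b], edges[b + 1]).upper()
                    theta = _gc_percent(seq)
                elif tot_bases[b] > 0:
                    theta = int(round(100.0 * gc_bases[b] / tot_bases[b]))
                else:
                    theta = 50
                mq0 = mq0_in_bin[b] / reads_in_bin[b] if reads_in_bin[b] else 0.0
                bins.append(
                    BinCount(gc_theta=theta, width=width, n_i=int(n_arr[b]), mq0_fraction=mq0)
                )

        if not bins and not windows:
            raise ValueError("no evidence region")
        return ObservedCounts(
            bins=bins,
            junctions=list(zip(d_counts, s_counts)),
            library_id=params.library_id,
            junction_gc=junction_gc,
        )
    finally:
        if own_aln:
            aln.close()
        if own_ref:
            ref.close()


def _gc_percent(seq: str) -> int:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 50
    gc = seq.count("G") + seq.count("C")
    return int(round(100.0 * gc / acgt))
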