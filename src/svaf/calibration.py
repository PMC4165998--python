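"""Genome-wide parameter initialization from randomly sampled regions.

Before any VAF is estimated, the library's sequencing characteristics are
measured from the alignment itself: median read length r, median insert
size t (outer distance, SAM template-length convention) with a robust
spread (1.4826 * MAD), the mean pair rate c (proper pairs per surveyed
bp), and a lookup table of the pair rate as a function of integer GC
percent used to normalize depth bins. By default ten 10 Mb regions are
sampled; centromere/telomere-like intervals can be excluded by supplying
them explicitly (BED-style, 0-based half-open).

The discordant-pair and soft-clip channel offsets v_d and v_s default to
0.8 and 0.7 — typical shortfalls of observed counts against the idealized
span/sequence-coverage rates in short-insert WGS — and can be trained from
a truth set with :func:`train_offsets`.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .types import GCRateTable, LibraryParams

DEFAULT_N_REGIONS = 10
DEFAULT_REGION_SIZE = 10_000_000
DEFAULT_MIN_SUPPORT = 50


def _open_aln(alignment):
    import pysam

    if isinstance(alignment, str):
        return pysam.AlignmentFile(alignment), True
    return alignment, False


def _overlaps(start: int, end: int, intervals) -> bool:
    return any(start < e and s < end for s, e in intervals)


def sample_calibration_regions(
    alignment,
    n_regions: int = DEFAULT_N_REGIONS,
    region_size: int = DEFAULT_REGION_SIZE,
    exclusions: Optional[dict] = None,
    seed: Optional[int] = None,
) -> list:
    """Sample ``n_regions`` genomic intervals of ``region_size`` bp.

    Contigs are chosen with probability proportional to the number of
    placements they can host; intervals overlapping ``exclusions``
    (mapping contig -> list of (start, end), 0-based half-open) are
    rejected and redrawn. Deterministic under a fixed ``seed``. Returns
    ``[(contig, start, end), ...]``.
    """
    if n_regions == 0:
        return []
    exclusions = exclusions or {}
    aln, own = _open_aln(alignment)
    try:
        hosts = [
            (name, length)
            for name, length in zip(aln.references, aln.lengths)
            if length >= region_size
        ]
    finally:
        if own:
            aln.close()
    if not hosts:
        raise ValueError(
            f"no contig can host a {region_size} bp calibration region"
        )
    rng = np.random.default_rng(seed)
    weights = np.array([length - region_size + 1 for _, length in hosts], dtype=float)
    weights /= weights.sum()
    regions = []
    attempts = 0
    while len(regions) < n_regions:
        attempts += 1
        if attempts > 1000 * n_regions:
            raise ValueError(
                "could not place calibration regions outside the exclusion set"
            )
        i = rng.choice(len(hosts), p=weights)
        name, length = hosts[i]
        start = int(rng.integers(0, length - region_size + 1))
        if _overlaps(start, start + region_size, exclusions.get(name, [])):
            continue
        regions.append((name, start, start + region_size))
    return regions


def estimate_library_params(
    alignment,
    regions: Sequence[tuple],
    *,
    library_id: Optional[str] = None,
    offset_vd: float = 0.8,
    offset_vs: float = 0.7,
) -> LibraryParams:
    """Estimate r, t, spread and c from proper pairs in ``regions``.

    r is the median aligned read length; t the median outer insert size
    (|TLEN|) of flagged proper pairs; the spread is 1.4826 * MAD of |TLEN|
    (robust to chimeric-pair outliers); c counts each proper pair once, at
    the leftmost aligned base of its left mate, divided by the surveyed bp.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    aln, own = _open_aln(alignment)
    read_lengths = []
    tlens = []
    n_pairs = 0
    surveyed = 0
    try:
        for chrom, start, end in regions:
            surveyed += end - start
            for read in aln.fetch(chrom, start, end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                if not start <= read.reference_start < end:
                    continue
                read_lengths.append(read.query_alignment_length)
                if read.is_proper_pair and read.template_length > 0:
                    tlens.append(read.template_length)
                    n_pairs += 1
    finally:
        if own:
            aln.close()
    if not tlens:
        raise ValueError("no proper pairs found in the calibration regions")
    tlens = np.asarray(tlens, dtype=float)
    t = float(np.median(tlens))
    spread = float(1.4826 * np.median(np.abs(tlens - t)))
    return LibraryParams(
        library_id=library_id or "lib0",
        read_length_r=float(np.median(read_lengths)),
        insert_median_t=t,
        insert_spread=spread,
        inserts_per_bp_c=n_pairs / surveyed,
        offset_vd=offset_vd,
        offset_vs=offset_vs,
    )


def build_gc_table(
    alignment,
    regions: Sequence[tuple],
    bin_width: int = 100,
    reference=None,
    *,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> GCRateTable:
    """Build the GC-percent -> pair-rate lookup from the sampled regions.

    Each region is tiled into ``bin_width`` bins; per bin, proper pairs are
    counted at the leftmost base of the left mate (the same convention used
    at estimation time, so rates cancel in the likelihood) and the bin's GC
    percent comes from ``reference`` when supplied, else from aligned read
    bases (an approximation, documented as such). Strata observed in fewer
    than ``min_support`` bins report the global mean rate.
    """
    import pysam

    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    aln, own = _open_aln(alignment)
    own_ref = isinstance(reference, str)
    ref = pysam.FastaFile(reference) if own_ref else reference

    pairs_by_gc = np.zeros(101, dtype=float)
    bp_by_gc = np.zeros(101, dtype=float)
    support = np.zeros(101, dtype=int)
    total_pairs = 0.0
    total_bp = 0.0
    try:
        for chrom, start, end in regions:
            edges = list(range(start, end, bin_width)) + [end]
            m = len(edges) - 1
            counts = np.zeros(m, dtype=int)
            gc_bases = np.zeros(m, dtype=float)
            tot_bases = np.zeros(m, dtype=float)
            for read in aln.fetch(chrom, start, end):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                ):
                    continue
                pos = read.reference_start
                if not start <= pos < end:
                    continue
                b = min((pos - start) // bin_width, m - 1)
                if read.is_proper_pair and read.template_length > 0:
                    counts[b] += 1
                if ref is None:
                    seq = (read.query_alignment_sequence or "").upper()
                    gc_bases[b] += seq.count("G") + seq.count("C")
                    tot_bases[b] += len(seq)
            for b in range(m):
                width = edges[b + 1] - edges[b]
                if ref is not None:
                    seq = ref.fetch(chrom, edges[b], edges[b + 1]).upper()
                    acgt = sum(seq.count(x) for x in "ACGT")
                    theta = int(round(100.0 * (seq.count("G") + seq.count("C")) / acgt)) if acgt else 50
                elif tot_bases[b] > 0:
                    theta = int(round(100.0 * gc_bases[b] / tot_bases[b]))
                else:
                    theta = 50
                pairs_by_gc[theta] += counts[b]
                bp_by_gc[theta] += width
                support[theta] += 1
                total_pairs += counts[b]
                total_bp += width
    finally:
        if own:
            aln.close()
        if own_ref:
            ref.close()

    global_rate = total_pairs / total_bp if total_bp else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(bp_by_gc > 0, pairs_by_gc / np.maximum(bp_by_gc, 1e-300), global_rate)
    return GCRateTable(rates, support, global_rate, min_support=min_support)


def train_offsets(
    alignment,
    truth_svs: Sequence[tuple],
    params: LibraryParams,
    gc: GCRateTable,
    **evidence_kwargs,
) -> tuple:
    """Train (v_d, v_s) from SVs with known allele fractions.

    Each offset is the ratio of the summed observed junction counts to the
    summed counts expected with the offset at 1, clamped to [0, 1]:
    systematic shortfalls of the aligner's discordant-pair and soft-clip
    reporting show up directly in this ratio.

    ``truth_svs`` is a list of ``(SVCall, true_p)``.
    """
    from .evidence import count_evidence
    from .model import expected_rates

    if not truth_svs:
        raise ValueError("truth set must be non-empty")
    unit = replace(params, offset_vd=1.0, offset_vs=1.0)
    obs_d = obs_s = exp_d = exp_s = 0.0
    for sv, p in truth_svs:
        counts = count_evidence(alignment, sv, unit, gc, **evidence_kwargs)
        rates = expected_rates(sv, counts, unit, gc)
        n_bins = len(counts.bins)
        for j, (d, s) in enumerate(counts.junctions):
            obs_d += d
            obs_s += s
            exp_d += rates[n_bins + 2 * j].beta * p
            exp_s += rates[n_bins + 2 * j + 1].beta * p
    if exp_d <= 0 or exp_s <= 0:
        raise ValueError("expected junction counts sum to zero; cannot train offsets")
    return (
        min(1.0, max(0.0, obs_d / exp_d)),
        min(1.0, max(0.0, obs_s / exp_s)),
    )
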