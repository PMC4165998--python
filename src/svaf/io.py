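"""File interfaces: SV-call parsing, calibration persistence, and the
end-to-end per-sample estimation pipeline.

Supported SV-call formats
-------------------------
* BreakDancer-style TSV: ``chr1 pos1 ori1 chr2 pos2 ori2 type size score``
  with 1-based positions and types DEL / INS / INV / ITX / CTX / DUP-like.
* BEDPE: ``chrom1 start1 end1 chrom2 start2 end2 name ...`` with 0-based
  half-open starts; the 7th column carries the SV type. Starts are shifted
  +1 on parse so everything downstream is 1-based.

Type aliases are normalized: DUP/ITD -> DUP, CTX/ITX -> TRA. Unknown types
are skipped with a warning; a file with no parseable record is an error.
"""

from __future__ import annotations

import logging
import os
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    build_gc_table,
    estimate_library_params,
    sample_calibration_regions,
)
from .evidence import DEFAULT_BIN_WIDTH, DEFAULT_K, DEFAULT_MQ0_THRESHOLD, count_evidence, filter_bins
from .model import GenotypePrior, expected_rates, genotype_and_score
from .types import GCRateTable, LibraryParams, ObservedCounts, SVCall

logger = logging.getLogger("svaf")

#: upper bound on the auto-chosen calibration region size (bp)
DEFAULT_REGION_AUTO = 10_000_000

_TYPE_ALIASES = {
    "DEL": "DEL",
    "DELETION": "DEL",
    "DUP": "DUP",
    "DUPLICATION": "DUP",
    "ITD": "DUP",
    "INV": "INV",
    "INVERSION": "INV",
    "TRA": "TRA",
    "TRANSLOCATION": "TRA",
    "CTX": "TRA",
    "ITX": "TRA",
}

RESULT_COLUMNS = [
    "sample",
    "chrom1",
    "pos1",
    "chrom2",
    "pos2",
    "sv_type",
    "size",
    "p_hat",
    "genotype",
    "var_score",
    "error_prob",
    "n_total",
    "d_counts",
    "s_counts",
    "bins_filtered",
    "channels_dropped",
    "note",
]


def _normalize_type(token: str) -> Optional[str]:
    return _TYPE_ALIASES.get(token.strip().upper())


def _sv_from_fields(chrom1, pos1, chrom2, pos2, svtype) -> SVCall:
    if svtype == "TRA":
        return SVCall(chrom1, pos1, chrom2, pos2, "TRA")
    lo, hi = (pos1, pos2) if pos1 < pos2 else (pos2, pos1)
    return SVCall(chrom1, lo, chrom1, hi, svtype)


def parse_sv_calls(path: str, format: str = "auto") -> list:
    """Parse SV calls from a BreakDancer-style TSV or a BEDPE file.

    Returns a list of :class:`SVCall` with 1-based positions. Lines that
    fail to parse (or carry unknown types) are skipped with a warning; if
    nothing parses, that is an error.
    """
    if format not in ("auto", "breakdancer", "bedpe"):
        raise ValueError(f"unknown format {format!r}")
    calls, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            fmt = format
            if fmt == "auto":
                # BreakDancer puts orientation strings (e.g. "37+0-") in
                # columns 3 and 6; BEDPE has integer end coordinates there.
                ori_like = (
                    len(fields) >= 7
                    and ("+" in fields[2] or "-" in fields[2])
                    and ("+" in fields[5] or "-" in fields[5])
                )
                fmt = "breakdancer" if ori_like else "bedpe"
            try:
                if fmt == "breakdancer":
                    chrom1, pos1, _, chrom2, pos2, _, svtype = fields[:7]
                    typ = _normalize_type(svtype)
                    if typ is None:
                        raise ValueError(f"unknown SV type {svtype!r}")
                    calls.append(
                        _sv_from_fields(chrom1, int(pos1), chrom2, int(pos2), typ)
                    )
                else:
                    chrom1, start1, _, chrom2, start2 = fields[0], fields[1], fields[2], fields[3], fields[4]
                    typ = _normalize_type(fields[6]) if len(fields) >= 7 else None
                    if typ is None:
                        raise ValueError("BEDPE line lacks a recognized type in column 7")
                    # 0-based starts -> 1-based positions
                    calls.append(
                        _sv_from_fields(chrom1, int(start1) + 1, chrom2, int(start2) + 1, typ)
                    )
            except (ValueError, IndexError) as exc:
                skipped += 1
                warnings.warn(f"skipping unparseable SV line ({exc}): {line[:80]}")
    if skipped:
        logger.info("parse_sv_calls: skipped %d unparseable line(s)", skipped)
    if not calls:
        raise ValueError(f"no parseable SV records in {path}")
    return calls


# ---------------------------------------------------------------------------
# Calibration persistence (plain-text key-value header + GC table)
# ---------------------------------------------------------------------------


def save_calibration(path: str, params: LibraryParams, gc: GCRateTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"library_id\t{params.library_id}\n")
        fh.write(f"read_length_r\t{params.read_length_r}\n")
        fh.write(f"insert_median_t\t{params.insert_median_t}\n")
        fh.write(f"insert_spread\t{params.insert_spread}\n")
        fh.write(f"inserts_per_bp_c\t{params.inserts_per_bp_c}\n")
        fh.write(f"offset_vd\t{params.offset_vd}\n")
        fh.write(f"offset_vs\t{params.offset_vs}\n")
        fh.write(f"gc_global_rate\t{gc.global_rate}\n")
        fh.write(f"gc_min_support\t{gc.min_support}\n")
        fh.write("#gc_theta\trate\tsupport\n")
        for theta in range(101):
            fh.write(f"{theta}\t{gc.rate_by_gc[theta]:.10g}\t{gc.support_by_gc[theta]}\n")


def load_calibration(path: str):
    kv = {}
    rates = np.zeros(101)
    support = np.zeros(101, dtype=int)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 2:
                kv[fields[0]] = fields[1]
            elif len(fields) == 3:
                theta = int(fields[0])
                rates[theta] = float(fields[1])
                support[theta] = int(fields[2])
    params = LibraryParams(
        library_id=kv.get("library_id", "lib0"),
        read_length_r=float(kv["read_length_r"]),
        insert_median_t=float(kv["insert_median_t"]),
        insert_spread=float(kv["insert_spread"]),
        inserts_per_bp_c=float(kv["inserts_per_bp_c"]),
        offset_vd=float(kv["offset_vd"]),
        offset_vs=float(kv["offset_vs"]),
    )
    gc = GCRateTable(
        rates, support, float(kv["gc_global_rate"]), min_support=int(kv["gc_min_support"])
    )
    return params, gc


# ---------------------------------------------------------------------------
# End-to-end estimation
# ---------------------------------------------------------------------------


def estimate_sv(
    alignment,
    sv: SVCall,
    params: LibraryParams,
    gc: GCRateTable,
    *,
    reference=None,
    bin_width: int = DEFAULT_BIN_WIDTH,
    mq0_threshold: float = DEFAULT_MQ0_THRESHOLD,
    k: float = DEFAULT_K,
    prior: Optional[GenotypePrior] = None,
    noise_floor_eps: Optional[float] = None,
) -> dict:
    """Extract evidence for one SV and estimate its VAF; returns a result row."""
    from .model import NOISE_FLOOR_EPS

    eps = NOISE_FLOOR_EPS if noise_floor_eps is None else noise_floor_eps
    counts = count_evidence(
        alignment, sv, params, gc, bin_width=bin_width, reference=reference, k=k
    )
    kept_bins = filter_bins(counts.bins, mq0_threshold)
    filtered = ObservedCounts(
        bins=kept_bins,
        junctions=counts.junctions,
        library_id=counts.library_id,
        junction_gc=counts.junction_gc,
    )
    rates = expected_rates(sv, filtered, params, gc)
    est = genotype_and_score(filtered, rates, prior, noise_floor_eps=eps)
    return {
        "chrom1": sv.chrom1,
        "pos1": sv.pos1,
        "chrom2": sv.chrom2,
        "pos2": sv.pos2,
        "sv_type": sv.sv_type,
        "size": sv.size if sv.size is not None else -1,
        "p_hat": est.p_hat,
        "genotype": est.genotype,
        "var_score": est.var_score,
        "error_prob": est.error_prob,
        "n_total": filtered.total_normal,
        "d_counts": ";".join(str(d) for d, _ in filtered.junctions),
        "s_counts": ";".join(str(s) for _, s in filtered.junctions),
        "bins_filtered": len(counts.bins) - len(kept_bins),
        "channels_dropped": sum(1 for r in rates if r.dropped),
        "note": "",
    }


def run_estimate(
    bam_paths: Sequence[str],
    sv_path: str,
    calibration_path: Optional[str] = None,
    out_path: Optional[str] = None,
    *,
    reference: Optional[str] = None,
    sv_format: str = "auto",
    bin_width: int = DEFAULT_BIN_WIDTH,
    mq0_threshold: float = DEFAULT_MQ0_THRESHOLD,
    k: float = DEFAULT_K,
    prior: Optional[GenotypePrior] = None,
    seed: int = 0,
    n_regions: int = 10,
    region_size: Optional[int] = None,
    exclusions: Optional[dict] = None,
) -> pd.DataFrame:
    """Estimate the VAF of every SV in ``sv_path`` in each sample independently.

    Per sample: load the calibration if ``calibration_path`` is given (or a
    cached one exists beside the BAM), otherwise calibrate from randomly
    sampled regions and cache the result next to the BAM. Then extract
    evidence and estimate each SV; per-SV failures become flagged rows
    rather than aborting the run. Writes a TSV when ``out_path`` is given.
    """
    import pysam

    with open(sv_path) as fh:
        has_records = any(
            line.strip() and not line.startswith("#") and not line.lower().startswith("track")
            for line in fh
        )
    svs = parse_sv_calls(sv_path, format=sv_format) if has_records else []
    if not svs:
        table = pd.DataFrame(columns=RESULT_COLUMNS)
        if out_path:
            table.to_csv(out_path, sep="\t", index=False)
        return table
    rows = []
    for bam_path in bam_paths:
        sample = os.path.basename(bam_path).rsplit(".", 1)[0]
        cache = (calibration_path or bam_path + ".svaf_calib.tsv")
        if os.path.exists(cache):
            params, gc = load_calibration(cache)
        else:
            with pysam.AlignmentFile(bam_path) as aln:
                rsize = region_size or min(
                    DEFAULT_REGION_AUTO, max(aln.lengths) // 2
                )
                regions = sample_calibration_regions(
                    aln, n_regions=n_regions, region_size=rsize,
                    exclusions=exclusions, seed=seed,
                )
                params = estimate_library_params(aln, regions, library_id=sample)
                gc = build_gc_table(aln, regions, bin_width=bin_width, reference=reference)
            save_calibration(cache, params, gc)
            logger.info("calibrated %s: r=%.0f t=%.0f c=%.4g", sample,
                        params.read_length_r, params.insert_median_t,
                        params.inserts_per_bp_c)
        with pysam.AlignmentFile(bam_path) as aln:
            for sv in svs:
                try:
                    row = estimate_sv(
                        aln, sv, params, gc, reference=reference,
                        bin_width=bin_width, mq0_threshold=mq0_threshold,
                        k=k, prior=prior,
                    )
                except Exception as exc:  # per-SV failure -> flagged row
                    logger.warning("SV %s:%d failed: %s", sv.chrom1, sv.pos1, exc)
                    row = {
                        "chrom1": sv.chrom1, "pos1": sv.pos1,
                        "chrom2": sv.chrom2, "pos2": sv.pos2,
                        "sv_type": sv.sv_type,
                        "size": sv.size if sv.size is not None else -1,
                        "p_hat": np.nan, "genotype": "NA",
                        "var_score": np.nan, "error_prob": np.nan,
                        "n_total": 0, "d_counts": "", "s_counts": "",
                        "bins_filtered": 0, "channels_dropped": 0,
                        "note": f"failed: {exc}",
                    }
                row["sample"] = sample
                rows.append(row)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out_path:
        table.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return table


def loh_screen(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Candidate loss-of-heterozygosity events from a tumor/normal pair.

    Keeps SVs whose VAF is heterozygous-like in the normal (0.45..0.55)
    and homozygous-like in the tumor (<= 0.05 or >= 0.95).
    """
    key = ["chrom1", "pos1", "chrom2", "pos2", "sv_type"]
    merged = tumor.merge(normal, on=key, suffixes=("_tumor", "_normal"))
    sel = (
        merged["p_hat_normal"].between(0.45, 0.55)
        & (
            merged["p_hat_tumor"].between(0.0, 0.05)
            | merged["p_hat_tumor"].between(0.95, 1.0)
        )
    )
    return merged[sel].reset_index(drop=True)
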