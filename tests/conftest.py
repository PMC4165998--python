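"""Shared fixtures: small synthetic BAMs with planted SVs.

All alignment fixtures are generated at test time by the package's own
read-level generator; nothing binary ships with the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from svaf import LibraryParams, SVCall, generate_fixture_bam

#: library settings used by every read-level fixture
FIXTURE_COVERAGE = 30.0
FIXTURE_PARAMS = dict(
    read_length_r=100,
    insert_median_t=500,
    insert_spread=50,
    inserts_per_bp_c=FIXTURE_COVERAGE / 200.0,  # pairs per bp at 30x, 100 bp reads
)


def make_params(**over) -> LibraryParams:
    kw = dict(FIXTURE_PARAMS)
    kw.update(over)
    return LibraryParams(**kw)


@pytest.fixture(scope="session")
def multi_sv_fixture(tmp_path_factory):
    """One 200 kb genome (plus a chr2 partner) with all four SV types planted.

    Layout (1-based): het DEL 40-45 kb (p=0.5), hom DEL 80-85 kb (p=1.0),
    DUP 110-115 kb (p=0.5), INV 140-145 kb (p=0.5), TRA chr1:170 kb to
    chr2:100 kb (p=0.5). The 10-30 kb stretch carries no SV and serves as
    the null locus.
    """
    out = tmp_path_factory.mktemp("fixture") / "multi"
    svs = [
        (SVCall("chr1", 40_000, "chr1", 45_000, "DEL"), 0.5),
        (SVCall("chr1", 80_000, "chr1", 85_000, "DEL"), 1.0),
        (SVCall("chr1", 110_000, "chr1", 115_000, "DUP"), 0.5),
        (SVCall("chr1", 140_000, "chr1", 145_000, "INV"), 0.5),
        (SVCall("chr1", 170_000, "chr2", 100_000, "TRA"), 0.5),
    ]
    params = make_params()
    res = generate_fixture_bam(
        200_000, svs, params, coverage=FIXTURE_COVERAGE, seed=20260901,
        out_prefix=str(out),
    )
    res["svs"] = svs
    res["params"] = params
    res["coverage"] = FIXTURE_COVERAGE
    return res


@pytest.fixture(scope="session")
def tumor_normal_fixture(tmp_path_factory):
    """A tumor/normal pair sharing one somatic het DEL (present only in tumor)."""
    root = tmp_path_factory.mktemp("pair")
    sv = SVCall("chr1", 60_000, "chr1", 65_000, "DEL")
    params = make_params()
    tumor = generate_fixture_bam(
        150_000, [(sv, 0.5)], params, coverage=FIXTURE_COVERAGE,
        seed=11, out_prefix=str(root / "tumor"),
    )
    normal = generate_fixture_bam(
        150_000, [(sv, 0.0)], params, coverage=FIXTURE_COVERAGE,
        seed=12, out_prefix=str(root / "normal"),
    )
    return {"sv": sv, "params": params, "tumor": tumor, "normal": normal}
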