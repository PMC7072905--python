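"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from rilmap import bincall, genmap, simpop

CHROM_BP = {"1": 30_000_000}
CHROM_CM = {"1": 130.0}


def perfect_bin_map(mosaics, chrom_bp, grid_bp=15_000):
    """Bin map built from the true (error-free) mosaic segments."""
    segs = [m.segments for m in mosaics]
    return bincall.build_bin_map(segs, chrom_bp, grid_bp)


@pytest.fixture(scope="session")
def small_population():
    """One-chromosome, 144-line F11 population with noisy 7.75x calls."""
    snps = simpop.simulate_parents(1, CHROM_BP, 0.332, 11)
    mosaics = simpop.simulate_ril_mosaics(CHROM_CM, CHROM_BP, 144, 11, 12)
    ocm = simpop.sample_origin_calls(mosaics, snps, 7.75, 0.01, 13)
    return {"snps": snps, "mosaics": mosaics, "ocm": ocm,
            "chrom_bp": CHROM_BP, "chrom_cm": CHROM_CM}


@pytest.fixture(scope="session")
def small_bin_map(small_population):
    segs = bincall.call_all_segments(small_population["ocm"], CHROM_BP)
    bm = bincall.build_bin_map(segs, CHROM_BP)
    gm = genmap.build_genetic_map(bm, "haldane")
    return {"segments": segs, "bin_matrix": bm, "genetic_map": gm}


@pytest.fixture(scope="session")
def single_qtl_phenotype(small_population):
    effects = pd.DataFrame({"chrom": ["1"], "pos_bp": [15_000_000], "effect": [1.0]})
    pheno = simpop.simulate_phenotypes(
        small_population["mosaics"], effects, (40.0, 60.0), 8.0, 14
    )
    return {"effects": effects, "phenotypes": pheno}
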