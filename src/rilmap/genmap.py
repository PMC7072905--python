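"""Genetic-map estimation over bin markers.

Adjacent-marker recombinant fractions observed in the RIL population are
converted to per-meiosis recombination fractions with the selfed-RIL
(Haldane-Waddington) relation R = 2r/(1+2r), then to cM with a map
function (Kosambi by default, Haldane available), and accumulated along
the physical marker order.  Heterozygous bin genotypes carry negligible
information at advanced selfing generations and are treated as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bincall import BinMatrix
from .simpop import AA, BB

MAP_FUNCTIONS = ("haldane", "kosambi")


@dataclass
class GeneticMap:
    """Per-marker cumulative cM positions, ordered as the bin map.

    ``table`` columns: chrom, bin_id, pos_cm, pos_bp (bin midpoint),
    start_bp, end_bp.  The first marker of each chromosome sits at 0 cM.
    """

    table: pd.DataFrame
    map_function: str = "kosambi"
    flags: list[str] = field(default_factory=list)

    def chrom_length_cm(self, chrom: str) -> float:
        sub = self.table[self.table["chrom"] == str(chrom)]
        return float(sub["pos_cm"].max()) if len(sub) else 0.0

    def total_length_cm(self) -> float:
        return float(
            self.table.groupby("chrom", sort=False)["pos_cm"].max().sum()
        )


def estimate_rf(
    genotypes_m1: np.ndarray, genotypes_m2: np.ndarray
) -> tuple[float, int, str | None]:
    """Observed recombinant line fraction between two markers.

    Counts lines homozygous (AA or BB) at both markers; the fraction with
    discordant genotypes is ``R_obs``.  Returns ``(R_obs, n_informative,
    flag)``; raw fractions above 0.5 are capped at 0.4999 and flagged, no
    informative lines yields ``(nan, 0, "no_informative")``.
    """
    g1 = np.asarray(genotypes_m1)
    g2 = np.asarray(genotypes_m2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    hom = np.isin(g1, (AA, BB)) & np.isin(g2, (AA, BB))
    n = int(hom.sum())
    if n == 0:
        return float("nan"), 0, "no_informative"
    r_obs = float((g1[hom] != g2[hom]).sum() / n)
    if r_obs > 0.5:
        return 0.4999, n, "capped"
    return r_obs, n, None


def ril_correct(r_obs: float) -> float:
    """Invert the selfed-RIL relation R = 2r/(1+2r): r = R / (2(1-R))."""
    if not 0 <= r_obs <= 0.5:
        raise ValueError("R_obs must lie in [0, 0.5]; cap upstream")
    return r_obs / (2.0 * (1.0 - r_obs))


def rf_expected_ril(r: float | np.ndarray) -> float | np.ndarray:
    """Forward selfed-RIL relation: observed R for meiotic r."""
    return 2.0 * r / (1.0 + 2.0 * r)


def map_distance(
    r: float, map_function: str = "kosambi", ceiling_cm: float = 50.0
) -> tuple[float, str | None]:
    """Map a recombination fraction to cM; Haldane or Kosambi.

    Haldane: d = -50 ln(1-2r); Kosambi: d = 25 ln((1+2r)/(1-2r)).
    Distances at or above ``ceiling_cm`` (including r = 0.5, which maps to
    infinity) are reported as the ceiling with a flag.
    """
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    if not 0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    if r >= 0.5:
        return ceiling_cm, "ceiling"
    if map_function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    if d >= ceiling_cm:
        return ceiling_cm, "ceiling"
    return float(d), None


def inverse_map_distance(d_cm: float | np.ndarray, map_function: str = "kosambi"):
    """cM back to recombination fraction (inverse of ``map_distance``)."""
    if map_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    d = np.asarray(d_cm, dtype=float)
    if map_function == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    else:
        r = 0.5 * np.tanh(d / 50.0)
    return r if r.ndim else float(r)


def build_genetic_map(
    bin_matrix: BinMatrix,
    map_function: str = "kosambi",
    ceiling_cm: float = 50.0,
) -> GeneticMap:
    """Cumulative cM positions for every bin marker, per chromosome.

    Marker order is the physical order (no reordering); each adjacent
    interval's distance is ``map_distance(ril_correct(estimate_rf(...)))``.
    Intervals with no informative lines contribute 0 cM and are flagged.
    """
    bins = bin_matrix.bins
    geno = bin_matrix.genotypes
    flags: list[str] = []
    rows = []
    for chrom in bins["chrom"].unique():
        idx = bin_matrix.chrom_slice(chrom)
        pos_cm = 0.0
        for k, j in enumerate(idx):
            if k > 0:
                r_obs, n_inf, flag = estimate_rf(geno[:, idx[k - 1]], geno[:, j])
                if flag:
                    flags.append(f"{chrom}:{bins.at[j, 'bin_id']}:{flag}")
                if n_inf == 0 or np.isnan(r_obs):
                    d = 0.0
                else:
                    d, dflag = map_distance(ril_correct(r_obs), map_function, ceiling_cm)
                    if dflag:
                        flags.append(f"{chrom}:{bins.at[j, 'bin_id']}:{dflag}")
                pos_cm += d
            rows.append(
                {
                    "chrom": chrom,
                    "bin_id": bins.at[j, "bin_id"],
                    "pos_cm": pos_cm,
                    "pos_bp": int((bins.at[j, "start_bp"] + bins.at[j, "end_bp"]) // 2),
                    "start_bp": int(bins.at[j, "start_bp"]),
                    "end_bp": int(bins.at[j, "end_bp"]),
                }
            )
    if flags:
        warnings.warn(f"{len(flags)} flagged marker intervals", stacklevel=2)
    return GeneticMap(table=pd.DataFrame(rows), map_function=map_function, flags=flags)
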