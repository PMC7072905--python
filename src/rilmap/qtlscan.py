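"""Interval mapping and composite interval mapping over a bin map.

The scan regresses line phenotypes on the expected genotype score
x = P(BB) - P(AA) at a grid of genome positions (Haley-Knott regression),
conditioning the genotype probabilities on the flanking informative bin
genotypes through the selfed-RIL transition R(d) = 2r(d)/(1+2r(d)).
Composite interval mapping (CIM) adds forward-selected background marker
covariates, dropping those within an exclusion window of the test
position.  Genome-wide significance comes from permutation of the
phenotype vector; QTL support intervals use the conventional 1.5-LOD
drop; the variance explained by a peak is 100*(1 - 10^(-2*LOD/n)).

Sign convention: parent B (LTH) scores +1, so a positive additive effect
means the LTH allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bincall import BinMatrix
from .genmap import GeneticMap, inverse_map_distance, rf_expected_ril
from .simpop import AA, BB

_EPS = 1e-12


@dataclass
class ProbGrid:
    """Per-position expected genotype scores for every line.

    ``x[chrom]`` has shape (n_lines, n_positions) holding
    P(BB) - P(AA) conditional on the flanking informative bin genotypes
    (1 at a typed marker, 0 when both flanks are missing).
    """

    pos_cm: dict[str, np.ndarray]
    pos_bp: dict[str, np.ndarray]
    x: dict[str, np.ndarray]
    line_ids: list[str]
    map_function: str = "kosambi"

    @property
    def chroms(self) -> list[str]:
        return list(self.pos_cm)

    def stacked(self) -> tuple[np.ndarray, pd.DataFrame]:
        """All chromosomes concatenated: (n_lines x P, position table)."""
        xs, rows = [], []
        for chrom in self.chroms:
            xs.append(self.x[chrom])
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos_cm": self.pos_cm[chrom], "pos_bp": self.pos_bp[chrom]}
                )
            )
        return np.hstack(xs), pd.concat(rows, ignore_index=True)


@dataclass
class Covariate:
    bin_index: int
    bin_id: str
    chrom: str
    pos_cm: float
    scores: np.ndarray  # over all lines, AA=-1, BB=+1, HET/missing=0


@dataclass
class ScanResult:
    table: pd.DataFrame  # chrom, pos_cm, pos_bp, lod, add_effect
    method: str = "IM"
    flags: list[str] = field(default_factory=list)

    def chrom_arrays(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)].reset_index(drop=True)

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


def marker_scores(bin_matrix: BinMatrix) -> np.ndarray:
    """Numeric genotype scores per bin: AA=-1, BB=+1, HET/missing=0."""
    g = bin_matrix.genotypes
    return np.where(g == BB, 1.0, np.where(g == AA, -1.0, 0.0))


def genotype_probabilities(
    bin_matrix: BinMatrix, genetic_map: GeneticMap, step_cm: float = 1.0
) -> ProbGrid:
    """Expected genotype scores on a cM grid, conditioned on flanking bins.

    Between the nearest informative (homozygous) flanking markers at map
    distances d1 and d2, parental-origin transition probabilities
    R(d) = 2r(d)/(1+2r(d)) (with r(d) from the inverse map function) give
    P(BB) by two-link chain conditioning; a missing flank leaves the
    marginal 1/2 on that side.
    """
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    n_lines = len(bin_matrix.line_ids)
    fn = genetic_map.map_function
    pos_cm: dict[str, np.ndarray] = {}
    pos_bp: dict[str, np.ndarray] = {}
    xs: dict[str, np.ndarray] = {}

    for chrom in bin_matrix.bins["chrom"].unique():
        idx = bin_matrix.chrom_slice(chrom)
        sub = genetic_map.table[genetic_map.table["chrom"] == chrom]
        mcm = sub["pos_cm"].to_numpy(dtype=float)
        mbp = sub["pos_bp"].to_numpy(dtype=float)
        L = mcm[-1]
        grid = np.arange(0.0, L, step_cm)
        if grid.size == 0 or grid[-1] < L:
            grid = np.append(grid, L)
        # cM -> bp by linear interpolation between marker midpoints
        gbp = np.interp(grid, mcm, mbp)

        x = np.zeros((n_lines, grid.size))
        geno = bin_matrix.genotypes[:, idx]
        for i in range(n_lines):
            hom = np.isin(geno[i], (AA, BB))
            if not hom.any():
                continue
            hcm = mcm[hom]
            s = np.where(geno[i][hom] == BB, 1.0, -1.0)
            li = np.searchsorted(hcm, grid, side="right") - 1
            ri = np.searchsorted(hcm, grid, side="left")
            has_l, has_r = li >= 0, ri < hcm.size
            d1 = np.where(has_l, grid - hcm[np.clip(li, 0, None)], 0.0)
            d2 = np.where(has_r, hcm[np.clip(ri, None, hcm.size - 1)] - grid, 0.0)
            R1 = rf_expected_ril(np.asarray(inverse_map_distance(d1, fn)))
            R2 = rf_expected_ril(np.asarray(inverse_map_distance(d2, fn)))
            gl = np.where(has_l, s[np.clip(li, 0, None)], 0.0)
            gr = np.where(has_r, s[np.clip(ri, None, hcm.size - 1)], 0.0)
            # chain weights for origin B at the test position
            wb1 = np.where(has_l, np.where(gl > 0, 1 - R1, R1), 0.5)
            wa1 = np.where(has_l, np.where(gl > 0, R1, 1 - R1), 0.5)
            wb2 = np.where(has_r, np.where(gr > 0, 1 - R2, R2), 0.5)
            wa2 = np.where(has_r, np.where(gr > 0, R2, 1 - R2), 0.5)
            pb = wb1 * wb2 / np.maximum(wb1 * wb2 + wa1 * wa2, _EPS)
            x[i] = 2.0 * pb - 1.0
        pos_cm[chrom] = grid
        pos_bp[chrom] = gbp
        xs[chrom] = x
    return ProbGrid(pos_cm=pos_cm, pos_bp=pos_bp, x=xs, line_ids=list(bin_matrix.line_ids),
                    map_function=fn)


def phenotype_vector(
    phenotypes: pd.DataFrame, line_ids: list[str], trait: str | None = None
) -> np.ndarray:
    """Line means (over replicates) aligned to ``line_ids``; NaN if absent."""
    df = phenotypes
    if trait is not None:
        df = df[df["trait"] == trait]
    means = df.groupby("line_id")["value"].mean()
    return np.array([means.get(l, np.nan) for l in line_ids], dtype=float)


def _residualize(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after regression on Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def _lod_from_resid(y_r: np.ndarray, X_r: np.ndarray, n: int, lod_ceiling: float):
    """Single-predictor LOD and effect for each residualised column of X_r."""
    rss_red = float(y_r @ y_r)
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    sxy = X_r.T @ y_r
    beta = np.where(sxx > _EPS, sxy / np.maximum(sxx, _EPS), 0.0)
    rss_full = np.maximum(rss_red - beta * sxy, 0.0)
    capped = rss_full <= _EPS * max(rss_red, 1.0)
    with np.errstate(divide="ignore"):
        lod = 0.5 * n * np.log10(np.maximum(rss_red, _EPS) / np.maximum(rss_full, _EPS))
    lod = np.where(capped, lod_ceiling, np.minimum(lod, lod_ceiling))
    lod = np.where(sxx > _EPS, lod, 0.0)
    return np.maximum(lod, 0.0), beta, bool(capped.any())


def scan(
    prob_grid: ProbGrid,
    phenotype: np.ndarray,
    covariates: list[Covariate] | None = None,
    method: str = "IM",
    exclusion_window_cm: float = 10.0,
    lod_ceiling: float = 50.0,
    min_lines: int = 10,
) -> ScanResult:
    """Haley-Knott genome scan; LOD = (n/2) log10(RSS_reduced / RSS_full).

    The reduced model keeps the intercept and any active covariates and
    omits only the genotype score.  Covariates within
    ``exclusion_window_cm`` of the test position (same chromosome) are
    dropped from both models at that position.  Lines with undefined
    phenotype are excluded.
    """
    method = method.upper()
    if method not in ("IM", "CIM"):
        raise ValueError("method must be IM or CIM")
    if method == "IM":
        covariates = []
    covariates = covariates or []

    y_all = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(y_all)
    n = int(mask.sum())
    if n < min_lines:
        raise ValueError(f"phenotype defined for {n} lines; need >= {min_lines}")
    y = y_all[mask]
    flags: list[str] = []
    if np.var(y) <= _EPS:
        flags.append("zero_phenotypic_variance")

    frames = []
    for chrom in prob_grid.chroms:
        grid = prob_grid.pos_cm[chrom]
        X = prob_grid.x[chrom][mask]
        lod = np.zeros(grid.size)
        eff = np.zeros(grid.size)
        if "zero_phenotypic_variance" not in flags:
            # group positions by their active covariate set
            if covariates:
                active_masks = []
                for c in covariates:
                    if c.chrom == chrom:
                        active_masks.append(np.abs(grid - c.pos_cm) > exclusion_window_cm)
                    else:
                        active_masks.append(np.ones(grid.size, dtype=bool))
                keys = np.array([m for m in active_masks]).T  # (P, n_cov)
                groups: dict[tuple, np.ndarray] = {}
                for p in range(grid.size):
                    groups.setdefault(tuple(keys[p]), []).append(p)
            else:
                groups = {(): list(range(grid.size))}
            for key, pos_list in groups.items():
                cols = [np.ones(n)] + [
                    covariates[k].scores[mask] for k, on in enumerate(key) if on
                ]
                Z = np.column_stack(cols)
                y_r = _residualize(Z, y[:, None])[:, 0]
                X_r = _residualize(Z, X[:, pos_list])
                l, b, capped = _lod_from_resid(y_r, X_r, n, lod_ceiling)
                lod[pos_list], eff[pos_list] = l, b
                if capped:
                    flags.append(f"{chrom}:lod_ceiling")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_cm": grid,
                    "pos_bp": prob_grid.pos_bp[chrom],
                    "lod": lod,
                    "add_effect": eff,
                }
            )
        )
    return ScanResult(table=pd.concat(frames, ignore_index=True), method=method, flags=flags)


def select_cim_covariates(
    bin_matrix: BinMatrix,
    genetic_map: GeneticMap,
    phenotype: np.ndarray,
    max_cov: int = 5,
) -> list[Covariate]:
    """Forward selection of background marker covariates by RSS reduction.

    Markers enter one at a time, each the one most reducing the residual
    sum of squares given those already selected; selection stops at
    ``max_cov`` markers or when no marker reduces the RSS.
    """
    if max_cov < 0:
        raise ValueError("max_cov must be >= 0")
    if max_cov == 0:
        return []
    y_all = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(y_all)
    y = y_all[mask]
    M_full = marker_scores(bin_matrix)
    M = M_full[mask]
    n = y.size
    cm_by_bin = genetic_map.table.set_index("bin_id")["pos_cm"]

    selected: list[int] = []
    Z = np.ones((n, 1))
    for _ in range(max_cov):
        y_r = _residualize(Z, y[:, None])[:, 0]
        M_r = _residualize(Z, M)
        sxx = np.einsum("ij,ij->j", M_r, M_r)
        sxy = M_r.T @ y_r
        red = np.where(sxx > _EPS, sxy**2 / np.maximum(sxx, _EPS), -np.inf)
        red[selected] = -np.inf
        j = int(np.argmax(red))
        if not np.isfinite(red[j]) or red[j] <= _EPS:
            break
        selected.append(j)
        Z = np.column_stack([Z, M[:, j]])

    out = []
    for j in selected:
        row = bin_matrix.bins.iloc[j]
        out.append(
            Covariate(
                bin_index=j,
                bin_id=row["bin_id"],
                chrom=str(row["chrom"]),
                pos_cm=float(cm_by_bin[row["bin_id"]]),
                scores=M_full[:, j],
            )
        )
    return out


def permutation_threshold(
    prob_grid: ProbGrid,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "IM",
    bin_matrix: BinMatrix | None = None,
    genetic_map: GeneticMap | None = None,
    max_cov: int = 5,
    exclusion_window_cm: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted across lines ``n_perm`` times; the
    threshold is the empirical (1-alpha) quantile (upper order statistic)
    of the genome-wide maximum LOD.  For CIM the covariate selection is
    redone inside every permutation, keeping the null exchangeable.
    Returns ``(threshold, max_lods)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    y_all = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(y_all)
    y = y_all[mask]
    n = y.size
    method = method.upper()

    if method == "IM":
        X, _ = prob_grid.stacked()
        X = X[mask]
        Xc = X - X.mean(axis=0)
        xn = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
        ok = xn > _EPS
        Y = np.empty((n, n_perm))
        for k in range(n_perm):
            Y[:, k] = rng.permutation(y)
        Yc = Y - Y.mean(axis=0)
        yn = np.sqrt(np.einsum("ij,ij->j", Yc, Yc))
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Xc[:, ok].T @ Yc) / np.outer(xn[ok], np.maximum(yn, _EPS))
        r2max = np.max(R**2, axis=0) if ok.any() else np.zeros(n_perm)
        max_lods = -0.5 * n * np.log10(np.maximum(1.0 - r2max, _EPS))
    else:
        if bin_matrix is None or genetic_map is None:
            raise ValueError("CIM permutations need bin_matrix and genetic_map")
        max_lods = np.empty(n_perm)
        for k in range(n_perm):
            y_perm = np.full_like(y_all, np.nan)
            y_perm[mask] = rng.permutation(y)
            covs = select_cim_covariates(bin_matrix, genetic_map, y_perm, max_cov)
            res = scan(prob_grid, y_perm, covs, "CIM", exclusion_window_cm)
            max_lods[k] = res.max_lod()

    threshold = float(np.quantile(max_lods, 1.0 - alpha, method="higher"))
    return threshold, max_lods


def support_interval(
    scan_result: ScanResult, chrom: str, peak_cm: float, drop: float = 1.5
) -> dict:
    """1.5-LOD support interval around a peak, linearly interpolated.

    Returns the widest contiguous interval around the peak where
    LOD >= peak_LOD - drop; endpoints are interpolated between grid
    positions on the cM scale and mapped to bp by interpolation along the
    grid; truncated at chromosome ends (flagged ``flat`` if the whole
    chromosome qualifies).
    """
    if drop <= 0:
        raise ValueError("drop must be positive")
    sub = scan_result.chrom_arrays(chrom)
    pos = sub["pos_cm"].to_numpy()
    bp = sub["pos_bp"].to_numpy()
    lod = sub["lod"].to_numpy()
    i = int(np.argmin(np.abs(pos - peak_cm)))
    thr = lod[i] - drop

    lo_cm = pos[0]
    for l in range(i - 1, -1, -1):
        if lod[l] < thr:
            t = (thr - lod[l]) / max(lod[l + 1] - lod[l], _EPS)
            lo_cm = pos[l] + t * (pos[l + 1] - pos[l])
            break
    hi_cm = pos[-1]
    for r in range(i + 1, pos.size):
        if lod[r] < thr:
            t = (thr - lod[r]) / max(lod[r - 1] - lod[r], _EPS)
            hi_cm = pos[r] - t * (pos[r] - pos[r - 1])
            break
    flag = "flat" if (lo_cm == pos[0] and hi_cm == pos[-1] and (lod >= thr).all()) else None
    return {
        "cm_lo": float(lo_cm),
        "cm_hi": float(hi_cm),
        "mb_lo": float(np.interp(lo_cm, pos, bp)) / 1e6,
        "mb_hi": float(np.interp(hi_cm, pos, bp)) / 1e6,
        "flag": flag,
    }


def var_explained(lod: float | np.ndarray, n_lines: int):
    """Percent phenotypic variance explained: 100 (1 - 10^(-2 LOD / n))."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * np.asarray(lod, dtype=float) / n_lines))


def qtl_report(
    scan_result: ScanResult,
    threshold: float,
    n_lines: int,
    drop: float = 1.5,
    trait: str = "LTG",
    distinct_dip: float = 1.0,
) -> pd.DataFrame:
    """One record per significant LOD peak, Table-style columns.

    Peaks on a chromosome are distinct when separated by a dip below
    ``threshold - distinct_dip``.  Each record carries the peak position
    (cM and Mb), the ``drop``-LOD support interval on both scales, the
    LOD, the variance explained, the additive effect and the parent whose
    allele increases the trait (LTH iff the effect is positive).
    """
    records = []
    for chrom in scan_result.table["chrom"].unique():
        sub = scan_result.chrom_arrays(chrom)
        pos = sub["pos_cm"].to_numpy()
        lod = sub["lod"].to_numpy()
        eff = sub["add_effect"].to_numpy()
        claimed = np.zeros(pos.size, dtype=bool)
        peaks = []
        while True:
            cand = np.flatnonzero((lod >= threshold) & ~claimed)
            if cand.size == 0:
                break
            i = cand[np.argmax(lod[cand])]
            lo = i
            while lo > 0 and lod[lo - 1] >= threshold - distinct_dip:
                lo -= 1
            hi = i
            while hi < pos.size - 1 and lod[hi + 1] >= threshold - distinct_dip:
                hi += 1
            claimed[lo : hi + 1] = True
            peaks.append(i)
        for i in sorted(peaks):
            si = support_interval(scan_result, chrom, pos[i], drop)
            records.append(
                {
                    "chrom": chrom,
                    "peak_cm": float(pos[i]),
                    "peak_mb": float(sub["pos_bp"].iloc[i]) / 1e6,
                    "ci_cm_lo": si["cm_lo"],
                    "ci_cm_hi": si["cm_hi"],
                    "ci_mb_lo": si["mb_lo"],
                    "ci_mb_hi": si["mb_hi"],
                    "lod": float(lod[i]),
                    "var_pct": float(var_explained(lod[i], n_lines)),
                    "add_effect": float(eff[i]),
                    "positive_allele": "LTH" if eff[i] > 0 else "SN265",
                }
            )
    df = pd.DataFrame(
        records,
        columns=[
            "chrom", "peak_cm", "peak_mb", "ci_cm_lo", "ci_cm_hi",
            "ci_mb_lo", "ci_mb_hi", "lod", "var_pct", "add_effect",
            "positive_allele",
        ],
    )
    # name peaks per chromosome: qLTG6, or qLTG7a / qLTG7b when several
    names = []
    counts = df.groupby("chrom")["lod"].transform("size") if len(df) else []
    seen: dict[str, int] = {}
    for k in range(len(df)):
        chrom = df["chrom"].iloc[k]
        seen[chrom] = seen.get(chrom, 0)
        suffix = "abcdefgh"[seen[chrom]] if counts.iloc[k] > 1 else ""
        names.append(f"q{trait}{chrom}{suffix}")
        seen[chrom] += 1
    df.insert(0, "name", names)
    return df
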