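"""Synthetic RIL population generator.

Emulates the data-generating process of a resequenced biparental rice RIL
study: two fully homozygous inbred parents differing at a dense panel of
biallelic SNPs; an F1 selfed by single-seed descent to an advanced
generation (F11 by default), each meiosis drawing an interference-free
(Poisson) number of crossovers; low-coverage resequencing that yields a
single parental-origin call per line and SNP, with Poisson depth (depth 0
= missing) and a per-call error rate; and an additive multi-QTL phenotype
anchored to the observed parental means.

Coordinates: crossovers are drawn on the genetic (cM) scale and mapped
linearly to physical (bp) positions, i.e. recombination density is uniform
within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes used throughout the package
AA, BB, HET, MISSING = 0, 1, 2, -1
GENO_LABELS = {AA: "AA", BB: "BB", HET: "HET", MISSING: "missing"}

# origin-call codes (per SNP site)
CALL_A, CALL_B, CALL_MISSING = 0, 1, -1


@dataclass
class Mosaic:
    """One line's genome as homozygosity segments per chromosome.

    ``segments[chrom]`` is an ordered list of ``(start_bp, end_bp, code)``
    with ``code in {AA, BB, HET}``; segments tile ``[1, length]`` (1-based
    inclusive) without gaps and adjacent segments differ in genotype.
    """

    segments: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def genotype_at(self, chrom: str, pos: int) -> int:
        for start, end, code in self.segments[chrom]:
            if start <= pos <= end:
                return code
        raise ValueError(f"position {chrom}:{pos} outside chromosome")

    def breakpoints(self, chrom: str) -> list[int]:
        """Physical positions of the segment junctions (bp of left segment end)."""
        segs = self.segments[chrom]
        return [end for _, end, _ in segs[:-1]]

    def het_fraction(self) -> float:
        tot = het = 0
        for segs in self.segments.values():
            for start, end, code in segs:
                ln = end - start + 1
                tot += ln
                if code == HET:
                    het += ln
        return het / tot if tot else 0.0


@dataclass
class OriginCallMatrix:
    """Per line x SNP parental-origin calls.

    ``calls[i, j]`` is CALL_A, CALL_B or CALL_MISSING for line ``i`` at the
    ``j``-th site of ``sites`` (ordered as the parental SNP set).
    """

    sites: pd.DataFrame  # columns: chrom, pos, allele_A, allele_B
    line_ids: list[str]
    calls: np.ndarray    # int8, shape (n_lines, n_sites)
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_ids), len(self.sites)):
            raise ValueError("calls shape does not match lines x sites")

    def line_calls(self, chrom: str, line_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions, calls) for one line restricted to one chromosome."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        return self.sites["pos"].to_numpy()[mask], self.calls[line_index, mask]


def simulate_parents(
    n_chrom: int,
    chrom_lengths_bp: dict[str, int] | list[int],
    snp_density_per_kb: float,
    seed: int,
) -> pd.DataFrame:
    """Draw a parental SNP set: positions uniform, sorted, deduplicated.

    Returns a DataFrame with columns chrom, pos (1-based), allele_A,
    allele_B (distinct bases); deterministic for a fixed seed.
    """
    if isinstance(chrom_lengths_bp, dict):
        lengths = {str(k): int(v) for k, v in chrom_lengths_bp.items()}
    else:
        lengths = {str(i + 1): int(v) for i, v in enumerate(chrom_lengths_bp)}
    if len(lengths) != n_chrom:
        raise ValueError("n_chrom does not match chrom_lengths_bp")
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if snp_density_per_kb <= 0:
        raise ValueError("snp_density_per_kb must be positive")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    frames = []
    for chrom, length in lengths.items():
        n = rng.poisson(length / 1000 * snp_density_per_kb)
        pos = np.unique(rng.integers(1, length + 1, size=n))
        a_idx = rng.integers(0, 4, size=pos.size)
        b_off = rng.integers(1, 4, size=pos.size)  # guarantees allele_B != allele_A
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele_A": bases[a_idx],
                    "allele_B": bases[(a_idx + b_off) % 4],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# meiosis on the genetic scale


def _slice_hap(hap: list[tuple[float, int]], a: float, b: float) -> list[tuple[float, int]]:
    """Segments of ``hap`` (list of (end_cM, origin)) overlapping (a, b]."""
    out = []
    prev = 0.0
    for end, origin in hap:
        if end > a and prev < b:
            out.append((min(end, b), origin))
        prev = end
        if prev >= b:
            break
    return out


def _meiosis(
    h1: list[tuple[float, int]],
    h2: list[tuple[float, int]],
    length_cm: float,
    rng: np.random.Generator,
) -> list[tuple[float, int]]:
    """One gamete from a plant's two haplotypes; crossovers ~ Poisson(L/100)."""
    n_co = rng.poisson(length_cm / 100.0)
    xs = np.sort(rng.uniform(0.0, length_cm, size=n_co))
    cur = int(rng.integers(0, 2))
    haps = (h1, h2)
    gamete: list[tuple[float, int]] = []
    a = 0.0
    for x in list(xs) + [length_cm]:
        if x > a:
            gamete.extend(_slice_hap(haps[cur], a, x))
        a = x
        cur ^= 1
    # merge adjacent equal-origin pieces
    merged: list[tuple[float, int]] = []
    for end, origin in gamete:
        if merged and merged[-1][1] == origin:
            merged[-1] = (end, origin)
        else:
            merged.append((end, origin))
    return merged


def _plant_to_mosaic_cm(
    h1: list[tuple[float, int]], h2: list[tuple[float, int]]
) -> list[tuple[float, int]]:
    """Diploid genotype segments (end_cM, code) from two haplotypes."""
    ends = sorted({e for e, _ in h1} | {e for e, _ in h2})
    segs: list[tuple[float, int]] = []

    def origin_at(hap, a, b):
        mid = 0.5 * (a + b)
        for end, origin in hap:
            if mid <= end:
                return origin
        return hap[-1][1]

    a = 0.0
    for b in ends:
        o1, o2 = origin_at(h1, a, b), origin_at(h2, a, b)
        code = AA if (o1 == 0 and o2 == 0) else BB if (o1 == 1 and o2 == 1) else HET
        if segs and segs[-1][1] == code:
            segs[-1] = (b, code)
        else:
            segs.append((b, code))
        a = b
    return segs


def _cm_segments_to_bp(
    segs: list[tuple[float, int]], length_cm: float, length_bp: int
) -> list[tuple[int, int, int]]:
    out: list[tuple[int, int, int]] = []
    start = 1
    for end_cm, code in segs:
        end_bp = length_bp if end_cm >= length_cm else int(round(end_cm / length_cm * length_bp))
        if end_bp < start:  # zero-length after rounding
            continue
        if out and out[-1][2] == code:
            out[-1] = (out[-1][0], end_bp, code)
        else:
            out.append((start, end_bp, code))
        start = end_bp + 1
    # make sure the tiling reaches the chromosome end
    if out and out[-1][1] != length_bp:
        s, _, c = out[-1]
        out[-1] = (s, length_bp, c)
    return out


def simulate_ril_mosaics(
    genetic_lengths_cm: dict[str, float] | list[float],
    chrom_lengths_bp: dict[str, int] | list[int],
    n_lines: int,
    n_generations: int,
    seed: int,
) -> list[Mosaic]:
    """Selfed single-seed-descent RIL genomes at generation F``n_generations``.

    Each line descends from an independent F1 (haplotypes all-A and all-B)
    through ``n_generations - 1`` rounds of selfing; every meiosis draws a
    Poisson(L/100) crossover count with uniform positions (Haldane model,
    no interference).  Expected heterozygous genome fraction at Ft is
    (1/2)^(t-1); expected breakpoints per line per chromosome approach 2L
    Morgans as t grows.
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2 (F2 onward)")
    if isinstance(genetic_lengths_cm, list):
        genetic_lengths_cm = {str(i + 1): v for i, v in enumerate(genetic_lengths_cm)}
    if isinstance(chrom_lengths_bp, list):
        chrom_lengths_bp = {str(i + 1): v for i, v in enumerate(chrom_lengths_bp)}
    if set(genetic_lengths_cm) != set(chrom_lengths_bp):
        raise ValueError("genetic and physical chromosome sets differ")
    if any(v <= 0 for v in genetic_lengths_cm.values()):
        raise ValueError("genetic lengths must be positive")

    rng = np.random.default_rng(seed)
    chroms = list(genetic_lengths_cm)
    mosaics = []
    for _ in range(n_lines):
        mosaic = Mosaic()
        for chrom in chroms:
            L = float(genetic_lengths_cm[chrom])
            h1: list[tuple[float, int]] = [(L, 0)]
            h2: list[tuple[float, int]] = [(L, 1)]
            for _gen in range(n_generations - 1):
                g1 = _meiosis(h1, h2, L, rng)
                g2 = _meiosis(h1, h2, L, rng)
                h1, h2 = g1, g2
            segs_cm = _plant_to_mosaic_cm(h1, h2)
            mosaic.segments[chrom] = _cm_segments_to_bp(
                segs_cm, L, int(chrom_lengths_bp[chrom])
            )
        mosaics.append(mosaic)
    return mosaics


def sample_origin_calls(
    mosaics: list[Mosaic],
    snps: pd.DataFrame,
    mean_depth: float,
    error_rate: float,
    seed: int,
    line_ids: list[str] | None = None,
) -> OriginCallMatrix:
    """Low-coverage per-site parental-origin calls.

    Per site, sequencing depth ~ Poisson(``mean_depth``); depth 0 yields a
    missing call, otherwise the call is the true parental origin of the
    covering segment (HET segments emit A or B with probability 1/2),
    flipped with probability ``error_rate``.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    n_lines, n_sites = len(mosaics), len(snps)
    if line_ids is None:
        line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    calls = np.full((n_lines, n_sites), CALL_MISSING, dtype=np.int8)

    by_chrom = {
        chrom: (sub.index.to_numpy(), sub["pos"].to_numpy())
        for chrom, sub in snps.groupby("chrom", sort=False)
    }
    for i, mosaic in enumerate(mosaics):
        for chrom, (idx, pos) in by_chrom.items():
            segs = mosaic.segments[chrom]
            ends = np.array([e for _, e, _ in segs])
            codes = np.array([c for _, _, c in segs])
            site_codes = codes[np.searchsorted(ends, pos)]
            truth = np.where(site_codes == BB, CALL_B, CALL_A).astype(np.int8)
            het = site_codes == HET
            if het.any():
                truth[het] = rng.integers(0, 2, size=int(het.sum()))
            depth = rng.poisson(mean_depth, size=pos.size)
            err = rng.random(pos.size) < error_rate
            obs = np.where(err, 1 - truth, truth).astype(np.int8)
            obs[depth == 0] = CALL_MISSING
            calls[i, idx] = obs
    lengths = (
        {chrom: segs[-1][1] for chrom, segs in mosaics[0].segments.items()}
        if mosaics
        else None
    )
    return OriginCallMatrix(
        sites=snps.reset_index(drop=True),
        line_ids=list(line_ids),
        calls=calls,
        chrom_lengths=lengths,
    )


def simulate_phenotypes(
    mosaics: list[Mosaic],
    qtl_effects: pd.DataFrame,
    parent_means: tuple[float, float],
    residual_sd: float,
    seed: int,
    trait: str = "germination_d6",
    line_ids: list[str] | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Additive multi-QTL phenotype anchored to the parental means.

    ``qtl_effects`` has columns chrom, pos_bp, effect; effects are relative
    weights with the sign giving the direction of the parent-B (LTH)
    allele.  They are rescaled so that their sum equals half the parental
    difference: an all-BB genome with zero residual returns the LTH parent
    mean and an all-AA genome the SN265 parent mean.  Per line,
    ``y = midparent + sum_j a_j x_j + e`` with x_j = +1 (BB), -1 (AA),
    0 (HET), e ~ Normal(0, residual_sd^2), truncated to [0, 100].
    """
    if not (0 <= parent_means[0] <= 100 and 0 <= parent_means[1] <= 100):
        raise ValueError("parent means must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    if line_ids is None:
        line_ids = [f"RIL{i + 1:03d}" for i in range(len(mosaics))]

    mid = 0.5 * (parent_means[0] + parent_means[1])
    half_diff = parent_means[1] - mid
    effects = qtl_effects.reset_index(drop=True)
    if len(effects):
        raw = effects["effect"].to_numpy(dtype=float)
        if raw.sum() == 0:
            raise ValueError("effect weights sum to zero; cannot anchor parents")
        scaled = raw * (half_diff / raw.sum())
    else:
        scaled = np.zeros(0)

    # genotype scores at the QTL positions (validates positions)
    x = np.zeros((len(mosaics), len(effects)))
    for j, row in effects.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos_bp"])
        for i, mosaic in enumerate(mosaics):
            if chrom not in mosaic.segments:
                raise ValueError(f"QTL chromosome {chrom!r} not simulated")
            end = mosaic.segments[chrom][-1][1]
            if not 1 <= pos <= end:
                raise ValueError(f"QTL position {chrom}:{pos} off chromosome (length {end})")
            g = mosaic.genotype_at(chrom, pos)
            x[i, j] = 1.0 if g == BB else -1.0 if g == AA else 0.0

    genetic = mid + x @ scaled
    rows = []
    for rep in range(1, n_replicates + 1):
        e = rng.normal(0.0, residual_sd, size=len(mosaics)) if residual_sd > 0 else 0.0
        y = np.clip(genetic + e, 0.0, 100.0)
        rows.append(
            pd.DataFrame(
                {"line_id": line_ids, "trait": trait, "value": y, "replicate": rep}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_major_locus_trait(
    mosaics: list[Mosaic],
    chrom: str,
    pos_bp: int,
    line_ids: list[str] | None = None,
    trait: str = "panicle_curvature",
) -> pd.DataFrame:
    """Fully penetrant single-locus trait (erect-panicle DEP1-like).

    A degenerate case of :func:`simulate_phenotypes`: one QTL, no residual
    noise, parent scores 0 (AA, curved-parent allele absent) and 100 (BB);
    heterozygotes score 50.  Scanning this as a quantitative trait yields a
    single saturated QTL at the locus.
    """
    effects = pd.DataFrame({"chrom": [chrom], "pos_bp": [pos_bp], "effect": [1.0]})
    return simulate_phenotypes(
        mosaics, effects, parent_means=(0.0, 100.0), residual_sd=0.0,
        seed=0, trait=trait, line_ids=line_ids,
    )
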