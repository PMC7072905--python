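"""Sliding-window genotype calling and 15-kb bin-map assembly.

Low-coverage origin calls are noisy and sparse, so per-line genotypes are
called over sliding windows of consecutive SNP calls (default 20 calls,
step 1): a window with an A:B call ratio of 15:5 or more extreme is a
homozygous call for the corresponding parent, anything in between is
heterozygous.  Runs of equal window genotypes shorter than ``min_run`` are
treated as call noise and absorbed.  Breakpoints are placed midway between
the flanking runs; per-line segments are then quantised onto a 15-kb grid
and grid cells with identical genotype vectors across the whole population
are merged into bin markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simpop import AA, BB, HET, MISSING, CALL_A, CALL_B, GENO_LABELS, OriginCallMatrix


@dataclass
class BinMatrix:
    """Population bin markers and per-line genotypes.

    ``bins`` columns: bin_id, chrom, start_bp, end_bp (1-based inclusive,
    tiling each chromosome); ``genotypes[i, j]`` is the genotype code of
    line ``i`` at bin ``j``.
    """

    bins: pd.DataFrame
    line_ids: list[str]
    genotypes: np.ndarray  # int8, (n_lines, n_bins)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())


def call_window_genotypes(
    calls: np.ndarray,
    window_size: int = 20,
    min_informative: int = 10,
    upper: float = 0.75,
    lower: float = 0.25,
) -> np.ndarray:
    """Genotype one line's ordered origin calls over sliding windows.

    Per window of ``window_size`` consecutive sites (step 1), with ``a``
    A-calls and ``b`` B-calls: AA when a/(a+b) >= ``upper`` (the 15:5
    rule, boundary inclusive), BB when a/(a+b) <= ``lower``, HET in
    between; missing when a+b < ``min_informative``.  Returns one genotype
    code per window (length ``n_sites - window_size + 1``).
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.size
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    if n < window_size:
        return np.zeros(0, dtype=np.int8)

    is_a = np.concatenate([[0], np.cumsum(calls == CALL_A)])
    is_b = np.concatenate([[0], np.cumsum(calls == CALL_B)])
    a = is_a[window_size:] - is_a[:-window_size]
    b = is_b[window_size:] - is_b[:-window_size]
    inf = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(inf > 0, a / np.maximum(inf, 1), np.nan)
    out = np.full(a.shape, HET, dtype=np.int8)
    out[frac >= upper] = AA
    out[frac <= lower] = BB
    out[inf < min_informative] = MISSING
    return out


def _absorb_short_runs(
    runs: list[tuple[int, list[int]]], min_run: int
) -> list[tuple[int, list[int]]]:
    """Absorb runs of fewer than ``min_run`` windows into a flanking run.

    A short run takes the genotype shared by its flanks when they agree;
    otherwise it joins the preceding run (ties resolved toward the
    preceding run); a short first/last run joins its only neighbour.
    Shortest runs are absorbed first (interior runs with agreeing flanks
    take precedence among equals, then leftmost); repeats until stable.
    """
    runs = [(g, list(w)) for g, w in runs]
    while len(runs) > 1:
        short = [
            (len(w), not (0 < k < len(runs) - 1 and runs[k - 1][0] == runs[k + 1][0]), k)
            for k, (_, w) in enumerate(runs)
            if len(w) < min_run
        ]
        if not short:
            break
        _, _, k = min(short)
        tgt = 1 if k == 0 else k - 1
        runs[k] = (runs[tgt][0], runs[k][1])
        # re-merge adjacent equal-genotype runs
        merged: list[tuple[int, list[int]]] = []
        for g, w in runs:
            if merged and merged[-1][0] == g:
                merged[-1] = (g, merged[-1][1] + w)
            else:
                merged.append((g, w))
        runs = merged
    return runs


def _collapse_het_transitions(
    runs: list[tuple[int, list[int]]], max_len: int
) -> list[tuple[int, list[int]]]:
    """Collapse short HET runs that are sliding-window transition bands.

    A clean homozygous junction necessarily produces a band of windows
    whose call ratio passes through the heterozygous zone, so a HET run
    of fewer than ``max_len`` windows between opposite homozygous runs is
    read as a single breakpoint: its windows are split half-and-half
    between the flanks.  Short HET runs with equal (or only one)
    homozygous neighbours are absorbed outright.  Long HET runs are kept:
    genuine residual heterozygous segments span many windows.
    """
    runs = [(g, list(w)) for g, w in runs]
    changed = True
    while changed:
        changed = False
        for k, (g, wins) in enumerate(runs):
            if g != HET or len(wins) >= max_len or len(runs) <= 1:
                continue
            left = runs[k - 1] if k > 0 else None
            right = runs[k + 1] if k < len(runs) - 1 else None
            if left is not None and right is not None and left[0] != right[0]:
                half = (len(wins) + 1) // 2
                left[1].extend(wins[:half])
                right[1][:0] = wins[half:]
                del runs[k]
            elif left is not None:
                left[1].extend(wins)
                del runs[k]
            else:
                right[1][:0] = wins
                del runs[k]
            # re-merge adjacent equal-genotype runs
            merged: list[tuple[int, list[int]]] = []
            for gg, ww in runs:
                if merged and merged[-1][0] == gg:
                    merged[-1][1].extend(ww)
                else:
                    merged.append((gg, ww))
            runs = merged
            changed = True
            break
    return runs


def detect_breakpoints(
    window_genotypes: np.ndarray,
    snp_positions: np.ndarray,
    chrom_length_bp: int,
    window_size: int = 20,
    min_run: int = 3,
    het_collapse: int | None = None,
) -> list[tuple[int, int, int]]:
    """Segment one line's chromosome from its window genotype sequence.

    Missing windows are dropped; consecutive equal genotypes form runs;
    runs shorter than ``min_run`` are absorbed (see ``_absorb_short_runs``)
    and short HET transition bands are collapsed into single junctions
    (see ``_collapse_het_transitions``; threshold ``het_collapse``,
    default 2x window_size).  Each window is anchored at its central SNP,
    and the breakpoint between two runs is placed at the midpoint between
    the last anchor SNP of the left run and the first anchor SNP of the
    right run.  The first and last runs are extended to the chromosome
    ends.  If every window is missing a single segment with the missing
    genotype is returned.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if het_collapse is None:
        het_collapse = 2 * window_size
    wg = np.asarray(window_genotypes, dtype=np.int8)
    pos = np.asarray(snp_positions)
    keep = np.flatnonzero(wg != MISSING)
    if keep.size == 0:
        return [(1, int(chrom_length_bp), MISSING)]

    # run-length encode over non-missing windows
    runs: list[tuple[int, list[int]]] = []
    for w in keep:
        g = int(wg[w])
        if runs and runs[-1][0] == g:
            runs[-1][1].append(int(w))
        else:
            runs.append((g, [int(w)]))
    runs = _absorb_short_runs(runs, min_run)
    runs = _collapse_het_transitions(runs, het_collapse)

    center = (window_size - 1) // 2
    segments: list[tuple[int, int, int]] = []
    start = 1
    for k, (g, wins) in enumerate(runs):
        if k == len(runs) - 1:
            end = int(chrom_length_bp)
        else:
            left_anchor = pos[wins[-1] + center]
            right_anchor = pos[runs[k + 1][1][0] + center]
            end = int((int(left_anchor) + int(right_anchor)) // 2)
        if segments and segments[-1][2] == g:
            segments[-1] = (segments[-1][0], end, g)
        else:
            segments.append((start, end, g))
        start = end + 1
    return segments


def segments_for_line(
    ocm: OriginCallMatrix,
    line_index: int,
    chrom_lengths_bp: dict[str, int],
    window_size: int = 20,
    min_informative: int = 10,
    min_run: int = 3,
) -> dict[str, list[tuple[int, int, int]]]:
    """Window-call and segment every chromosome of one line."""
    out = {}
    for chrom, length in chrom_lengths_bp.items():
        pos, calls = ocm.line_calls(str(chrom), line_index)
        wg = call_window_genotypes(calls, window_size, min_informative)
        if wg.size == 0:
            out[str(chrom)] = [(1, int(length), MISSING)]
            continue
        out[str(chrom)] = detect_breakpoints(wg, pos, int(length), window_size, min_run)
    return out


def call_all_segments(
    ocm: OriginCallMatrix,
    chrom_lengths_bp: dict[str, int],
    window_size: int = 20,
    min_informative: int = 10,
    min_run: int = 3,
) -> list[dict[str, list[tuple[int, int, int]]]]:
    return [
        segments_for_line(ocm, i, chrom_lengths_bp, window_size, min_informative, min_run)
        for i in range(len(ocm.line_ids))
    ]


def build_bin_map(
    segment_sets: list[dict[str, list[tuple[int, int, int]]]],
    chrom_lengths_bp: dict[str, int],
    grid_bp: int = 15_000,
    line_ids: list[str] | None = None,
) -> BinMatrix:
    """Quantise per-line segments onto a grid and merge into bin markers.

    Each chromosome is tiled into ``grid_bp`` cells (the last cell may be
    short); a line's genotype in a cell is the genotype of the segment
    covering the cell midpoint.  Adjacent cells whose genotype vector over
    ALL lines is identical are merged into one bin marker, so every bin
    boundary is a recombination breakpoint in at least one line.
    """
    if grid_bp <= 0:
        raise ValueError("grid_bp must be positive")
    if not segment_sets:
        raise ValueError("no lines provided")
    n_lines = len(segment_sets)
    if line_ids is None:
        line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]

    bin_rows = []
    geno_cols = []
    for chrom, length in ((str(c), int(v)) for c, v in chrom_lengths_bp.items()):
        n_cells = int(np.ceil(length / grid_bp))
        starts = np.arange(n_cells, dtype=np.int64) * grid_bp + 1
        ends = np.minimum(starts + grid_bp - 1, length)
        mids = (starts + ends) // 2

        cell_geno = np.empty((n_lines, n_cells), dtype=np.int8)
        for i, segs in enumerate(segment_sets):
            seg = segs[chrom]
            seg_ends = np.array([e for _, e, _ in seg], dtype=np.int64)
            seg_codes = np.array([g for _, _, g in seg], dtype=np.int8)
            cell_geno[i] = seg_codes[
                np.minimum(np.searchsorted(seg_ends, mids), len(seg) - 1)
            ]

        # merge grid cells with identical genotype vectors across all lines
        new_bin = np.ones(n_cells, dtype=bool)
        if n_cells > 1:
            new_bin[1:] = (cell_geno[:, 1:] != cell_geno[:, :-1]).any(axis=0)
        bin_idx = np.cumsum(new_bin) - 1
        n_bins = int(bin_idx[-1]) + 1
        for b in range(n_bins):
            cells = np.flatnonzero(bin_idx == b)
            bin_rows.append((chrom, int(starts[cells[0]]), int(ends[cells[-1]])))
        geno_cols.append(cell_geno[:, new_bin])

    bins = pd.DataFrame(bin_rows, columns=["chrom", "start_bp", "end_bp"])
    bins.insert(0, "bin_id", [f"bin{k + 1:04d}" for k in range(len(bins))])
    return BinMatrix(bins=bins, line_ids=list(line_ids), genotypes=np.hstack(geno_cols))


def mean_marker_spacing(length: float, n_markers: int) -> float:
    """Mean adjacent-marker spacing as chromosome length / marker count."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return length / n_markers


def summarize_map_table(per_chrom: pd.DataFrame) -> pd.DataFrame:
    """Add spacing columns and a totals row to a per-chromosome map table.

    Expects columns chrom, n_markers, genetic_length_cm, physical_length_mb.
    Spacing uses the length / marker-count convention on each scale.
    """
    df = per_chrom.copy()
    df["avg_cm_per_marker"] = df["genetic_length_cm"] / df["n_markers"]
    df["avg_kb_per_marker"] = df["physical_length_mb"] * 1000 / df["n_markers"]
    total = pd.DataFrame(
        {
            "chrom": ["total"],
            "n_markers": [df["n_markers"].sum()],
            "genetic_length_cm": [df["genetic_length_cm"].sum()],
            "physical_length_mb": [df["physical_length_mb"].sum()],
            "avg_cm_per_marker": [df["genetic_length_cm"].sum() / df["n_markers"].sum()],
            "avg_kb_per_marker": [
                df["physical_length_mb"].sum() * 1000 / df["n_markers"].sum()
            ],
        }
    )
    return pd.concat([df, total], ignore_index=True)


def binmap_summary(bin_matrix: BinMatrix, genetic_map) -> pd.DataFrame:
    """Per-chromosome map characteristics from a bin map and genetic map.

    Marker count, genetic (cM) and physical (Mb) lengths, mean spacings
    (length / marker count on both scales) and adjacent-marker gap
    statistics (start-to-start distances), plus a totals row.
    """
    table = genetic_map.table
    rows = []
    for chrom in bin_matrix.bins["chrom"].unique():
        sub_bins = bin_matrix.bins[bin_matrix.bins["chrom"] == chrom]
        sub_map = table[table["chrom"] == chrom]
        n = len(sub_bins)
        cm_len = float(sub_map["pos_cm"].max()) if len(sub_map) else 0.0
        mb_len = float(sub_bins["end_bp"].max()) / 1e6
        gaps = np.diff(sub_bins["start_bp"].to_numpy())
        rows.append(
            {
                "chrom": chrom,
                "n_markers": n,
                "genetic_length_cm": cm_len,
                "physical_length_mb": mb_len,
                "lt1mb_gaps": int((gaps < 1e6).sum()) if gaps.size else 0,
                "min_gap_kb": float(gaps.min() / 1e3) if gaps.size else np.nan,
                "max_gap_mb": float(gaps.max() / 1e6) if gaps.size else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    out = summarize_map_table(df[["chrom", "n_markers", "genetic_length_cm", "physical_length_mb"]])
    return out.merge(df[["chrom", "lt1mb_gaps", "min_gap_kb", "max_gap_mb"]], on="chrom", how="left")


def genotype_labels(codes: np.ndarray) -> np.ndarray:
    """Map integer genotype codes to the AA/BB/HET/missing labels."""
    return np.vectorize(GENO_LABELS.get)(codes)
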