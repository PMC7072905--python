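"""Substitution mapping from key homozygous recombinants.

A QTL detected at coarse resolution is refined by genotyping lines that
carry recombination breakpoints inside the region at a panel of fine
markers, progeny-testing each line into a tolerant or sensitive class,
and intersecting the per-line regions where the homozygous genotype is
concordant with the phenotype class.  Genes overlapping the delimited
interval are then pulled from the annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RecombinantPanel:
    """Fine markers, homozygous genotypes and phenotype classes.

    ``markers``: DataFrame (marker_id, chrom, pos_bp), ordered by position;
    ``genotypes``: DataFrame indexed by line, one column per marker_id,
    entries "AA" (sensitive-parent, SN265) or "BB" (tolerant-parent, LTH);
    ``classes``: line -> "tolerant" | "sensitive" | None (unclassified).
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame
    classes: dict[str, str | None]

    def __post_init__(self) -> None:
        pos = self.markers["pos_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError("fine markers must be ordered by position")
        bad = set(self.genotypes.columns) - set(self.markers["marker_id"])
        if bad:
            raise ValueError(f"genotype columns without marker records: {sorted(bad)}")
        vals = set(np.unique(self.genotypes.to_numpy()))
        if not vals <= {"AA", "BB"}:
            raise ValueError("key recombinant lines must be homozygous (AA/BB) everywhere")


@dataclass
class FineMapInterval:
    left_marker: str
    right_marker: str
    left_bp: int
    right_bp: int
    flags: list[str] = field(default_factory=list)


def classify_progeny(
    progeny: pd.DataFrame,
    parent_means: tuple[float, float],
    rule: str = "t_test",
    alpha: float = 0.05,
) -> dict[str, str | None]:
    """Phenotype class per line from progeny germination values.

    ``progeny`` has columns line_id, value (one row per progeny replicate).
    ``parent_means`` is (sensitive, tolerant) = (SN265, LTH).  The
    ``midpoint`` rule classes a line tolerant iff its mean exceeds the
    midparent (ties unclassified).  The ``t_test`` rule assigns the class
    of whichever parent mean the line's replicates do not differ from at
    level ``alpha`` (one-sample t-test); ambiguous or doubly-rejected
    lines stay unclassified.
    """
    if rule not in ("midpoint", "t_test"):
        raise ValueError("rule must be 'midpoint' or 't_test'")
    if len(progeny) == 0:
        raise ValueError("empty progeny set")
    sens_mean, tol_mean = float(parent_means[0]), float(parent_means[1])
    if sens_mean > tol_mean:
        sens_mean, tol_mean = tol_mean, sens_mean
    mid = 0.5 * (sens_mean + tol_mean)

    out: dict[str, str | None] = {}
    for line, grp in progeny.groupby("line_id"):
        vals = grp["value"].to_numpy(dtype=float)
        if rule == "midpoint":
            m = vals.mean()
            out[line] = "tolerant" if m > mid else "sensitive" if m < mid else None
            continue
        if vals.size < 2 or np.std(vals) == 0:
            # degenerate replicates: fall back to the midpoint decision
            m = vals.mean()
            out[line] = "tolerant" if m > mid else "sensitive" if m < mid else None
            continue
        p_tol = stats.ttest_1samp(vals, tol_mean).pvalue
        p_sen = stats.ttest_1samp(vals, sens_mean).pvalue
        tol_ok, sen_ok = p_tol >= alpha, p_sen >= alpha
        out[line] = "tolerant" if tol_ok and not sen_ok else (
            "sensitive" if sen_ok and not tol_ok else None
        )
    return out


def delimit_interval(panel: RecombinantPanel) -> FineMapInterval:
    """Narrowest marker-bounded interval consistent with every line.

    Each classified line's candidate region is the set of markers where
    its genotype equals the phenotype-concordant parent (tolerant -> BB,
    sensitive -> AA); the QTL must lie in the intersection of these
    regions.  Contradictory lines (empty intersection) raise an error
    naming them; a panel with no informative recombinant returns the
    whole region with a warning.
    """
    marker_ids = list(panel.markers["marker_id"])
    pos = panel.markers.set_index("marker_id")["pos_bp"]
    lines = [l for l in panel.genotypes.index if panel.classes.get(l) is not None]
    dropped = [l for l in panel.genotypes.index if panel.classes.get(l) is None]
    if dropped:
        warnings.warn(f"unclassified lines excluded: {dropped}", stacklevel=2)
    if not lines:
        raise ValueError("no classified lines in panel")

    concordant = {"tolerant": "BB", "sensitive": "AA"}
    masks = {}
    for line in lines:
        want = concordant[panel.classes[line]]
        masks[line] = panel.genotypes.loc[line, marker_ids].to_numpy() == want

    inter = np.logical_and.reduce(list(masks.values()))
    if not inter.any():
        conflicting = [l for l in lines if not masks[l].any()] or lines
        raise ValueError(
            "contradictory recombinant lines (no marker concordant in all): "
            + ", ".join(conflicting)
        )

    flags = []
    if inter.all():
        flags.append("no_informative_recombinant")
        warnings.warn("no informative recombinant; whole region returned", stacklevel=2)

    # longest contiguous run of fully-concordant markers (ties -> leftmost)
    runs = []
    start = None
    for k, ok in enumerate(list(inter) + [False]):
        if ok and start is None:
            start = k
        elif not ok and start is not None:
            runs.append((k - start, start, k - 1))
            start = None
    length, lo, hi = max(runs, key=lambda t: (t[0], -t[1]))
    if len(runs) > 1:
        flags.append("noncontiguous_intersection")

    return FineMapInterval(
        left_marker=marker_ids[lo],
        right_marker=marker_ids[hi],
        left_bp=int(pos.iloc[lo]),
        right_bp=int(pos.iloc[hi]),
        flags=flags,
    )


def load_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Normalise gene coordinates to start <= end (minus-strand entries
    are printed reversed in some annotation tables)."""
    df = annotation.copy()
    s = df[["start_bp", "end_bp"]].min(axis=1)
    e = df[["start_bp", "end_bp"]].max(axis=1)
    df["start_bp"], df["end_bp"] = s, e
    return df


def candidate_genes(interval_bp: tuple[int, int], annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping the interval by >= 1 bp, ordered by start."""
    lo, hi = int(interval_bp[0]), int(interval_bp[1])
    if lo > hi:
        lo, hi = hi, lo
    df = load_annotation(annotation)
    hit = df[(df["start_bp"] <= hi) & (df["end_bp"] >= lo)]
    return hit.sort_values("start_bp").reset_index(drop=True)
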