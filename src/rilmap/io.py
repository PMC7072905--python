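"""Readers and writers for the pipeline's interchange formats.

Origin calls travel as a minimal VCF (one sample per RIL line; 0/0 =
parent-A/SN265 origin, 1/1 = parent-B/LTH origin, ./. = missing), which
slots the pipeline in directly after reference-based variant calling and
parent polarisation.  Phenotypes are CSV; bin maps, genetic maps, scans
and QTL reports are TSV; thresholds, intervals and the run manifest are
JSON; gene annotation is TSV or GFF3 (gene features).
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .bincall import BinMatrix
from .genmap import GeneticMap
from .qtlscan import ScanResult
from .simpop import (
    AA, BB, HET, MISSING, CALL_A, CALL_B, CALL_MISSING,
    GENO_LABELS, OriginCallMatrix,
)

_LABEL_CODES = {v: k for k, v in GENO_LABELS.items()}


def write_calls_vcf(path, ocm: OriginCallMatrix) -> None:
    """Write origin calls as a minimal VCF (0/0, 1/1, ./.)."""
    gt = {CALL_A: "0/0", CALL_B: "1/1", CALL_MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rilmap\n")
        if ocm.chrom_lengths:
            for chrom, length in ocm.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ocm.line_ids)
            + "\n"
        )
        sites = ocm.sites
        for j in range(len(sites)):
            row = [
                str(sites["chrom"].iloc[j]),
                str(int(sites["pos"].iloc[j])),
                ".",
                str(sites["allele_A"].iloc[j]),
                str(sites["allele_B"].iloc[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(c)] for c in ocm.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def read_calls_vcf(path) -> OriginCallMatrix:
    """Read a per-line origin-call VCF back into an OriginCallMatrix.

    0/0 maps to a parent-A call, 1/1 to parent-B, ./. to missing;
    heterozygous genotypes are mapped to missing with a counted warning;
    multiallelic genotype codes or unsorted positions are errors.
    """
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else None

    rows, cols = [], []
    n_het = 0
    last: dict[str, int] = {}
    for k, v in enumerate(vcf):
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(f"unsorted positions at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        calls = np.empty(len(line_ids), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                calls[i] = CALL_MISSING
            elif a == 0 and b == 0:
                calls[i] = CALL_A
            elif a == 1 and b == 1:
                calls[i] = CALL_B
            elif {a, b} == {0, 1}:
                calls[i] = CALL_MISSING
                n_het += 1
            else:
                raise ValueError(
                    f"unknown genotype code {a}/{b} at record {k + 1} ({v.CHROM}:{v.POS})"
                )
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0] if v.ALT else "N"))
        cols.append(calls)
    if n_het:
        warnings.warn(f"{n_het} heterozygous VCF genotypes mapped to missing", stacklevel=2)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "allele_A", "allele_B"])
    calls = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(line_ids), 0), np.int8)
    return OriginCallMatrix(sites=sites, line_ids=line_ids, calls=calls, chrom_lengths=lengths)


def write_phenotypes_csv(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"line_id", "trait", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV lacks columns: {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df


def write_bins_tsv(path, bin_matrix: BinMatrix) -> None:
    """Bin map as TSV: bin_id, chrom, start_bp, end_bp, one column per line."""
    labels = pd.DataFrame(
        {
            line: [GENO_LABELS[int(c)] for c in bin_matrix.genotypes[i]]
            for i, line in enumerate(bin_matrix.line_ids)
        }
    )
    df = pd.concat([bin_matrix.bins.reset_index(drop=True), labels], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_bins_tsv(path) -> BinMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["bin_id", "chrom", "start_bp", "end_bp"]
    line_ids = [c for c in df.columns if c not in meta]
    geno = np.array(
        [[_LABEL_CODES[v] for v in df[line]] for line in line_ids], dtype=np.int8
    )
    return BinMatrix(bins=df[meta].copy(), line_ids=line_ids, genotypes=geno)


def write_map_tsv(path, genetic_map: GeneticMap) -> None:
    df = genetic_map.table.copy()
    df["map_function"] = genetic_map.map_function
    df.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fn = str(df["map_function"].iloc[0]) if "map_function" in df else "kosambi"
    return GeneticMap(table=df.drop(columns=["map_function"], errors="ignore"),
                      map_function=fn)


def write_scan_tsv(path, scan_result: ScanResult) -> None:
    scan_result.table.to_csv(path, sep="\t", index=False)


def read_scan_tsv(path) -> ScanResult:
    return ScanResult(table=pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_report_tsv(path, report: pd.DataFrame) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_genes(path) -> pd.DataFrame:
    """Gene annotation from TSV (gene_id, start_bp, end_bp[, product]) or
    GFF3 (rows of type 'gene'); coordinates are NOT normalised here."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS, dtype={"seqid": str})
        df = df[df["type"] == "gene"].copy()
        ids = df["attributes"].map(
            lambda s: (re.search(r"(?:^|;)(?:ID|Name)=([^;]+)", s) or [None, "unknown"])[1]
        )
        out = pd.DataFrame(
            {
                "gene_id": ids.to_numpy(),
                "start_bp": df["start"].astype(int).to_numpy(),
                "end_bp": df["end"].astype(int).to_numpy(),
                "product": df["attributes"].to_numpy(),
            }
        )
        return out.reset_index(drop=True)
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "start_bp", "end_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if "product" not in df.columns:
        df["product"] = ""
    return df
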