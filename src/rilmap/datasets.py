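"""Published reference values for the SN265 x LTH rice RIL population.

These small tables are the published end points of the real-data analysis
(bin-map characteristics per chromosome, the eleven low-temperature
germinability QTLs, and the annotated genes in the fine-mapped qLTG6
region).  They serve two purposes: the reporting conventions implemented
in this package can be checked against them, and the simulator uses them
as realistic defaults (chromosome sizes, QTL placement, effect sizes).

Coordinates are on the Os-Nipponbare-Reference-IRGSP-1.0 assembly.
"""

from io import StringIO

import pandas as pd

# Per-chromosome characteristics of the published high-density bin map.
_MAP_SUMMARY_TSV = """\
chrom	n_markers	genetic_length_cm	physical_length_mb	lt1mb_gaps	min_gap_kb	max_gap_mb
1	254	338.65	42.93	246	15.27	3.16
2	254	227.11	31.61	252	15.47	3.45
3	313	284.80	36.14	310	15.06	1.57
4	281	300.18	34.29	275	15.63	1.91
5	239	269.15	29.68	235	15.32	1.08
6	247	181.10	28.63	244	15.53	3.63
7	187	217.94	29.23	184	17.18	1.46
8	238	193.86	28.12	237	15.02	0.99
9	188	111.32	22.30	185	15.89	1.92
10	234	199.84	22.99	230	15.77	1.27
11	186	323.32	28.49	183	15.01	3.48
12	207	192.85	26.70	202	15.63	2.33
"""

# The eleven reported day-6 15 degC germination QTLs.  add_effect is signed
# with the LTH allele positive; positive_allele names the parent whose
# allele raises germination.
_QTL_TSV = """\
name	chrom	peak_cm	peak_mb	ci_cm_lo	ci_cm_hi	ci_mb_lo	ci_mb_hi	lod	var_pct	add_effect	positive_allele
qLTG1	1	116.34	16.90	103.19	128.81	11.48	19.34	5.59	16.40	10.16	LTH
qLTG3	3	3.95	1.10	0.00	10.78	0.00	1.31	4.71	14.02	9.18	LTH
qLTG4	4	54.58	6.27	36.64	77.67	6.10	11.41	4.85	14.43	-9.30	SN265
qLTG6	6	0.18	1.34	0.18	1.07	0.34	0.74	3.64	11.05	8.13	LTH
qLTG7a	7	104.99	8.88	87.28	107.84	6.98	9.21	4.98	14.72	9.80	LTH
qLTG7b	7	152.12	20.32	148.13	162.80	18.93	21.76	7.39	21.04	11.26	LTH
qLTG9a	9	4.31	6.07	4.35	8.38	5.91	6.83	4.17	12.53	8.68	LTH
qLTG9b	9	79.24	15.27	71.69	102.85	14.91	21.38	5.29	15.60	-9.76	SN265
qLTG10	10	13.93	1.60	8.55	14.06	1.20	1.60	7.38	21.00	12.00	LTH
qLTG12a	12	6.17	0.87	4.72	16.25	0.86	2.35	5.14	15.20	9.65	LTH
qLTG12b	12	131.25	22.79	111.25	145.46	21.05	25.16	3.41	10.30	-8.12	SN265
"""

# Annotated genes in the 45.8-kb fine-mapped qLTG6 interval on chromosome 6.
# Coordinates as printed; LOC_Os06g01270 is listed with reversed (minus
# strand) coordinates and is normalised on load by finemap.load_annotation.
_QLTG6_GENES_TSV = """\
gene_id	start_bp	end_bp	product
LOC_Os06g01250	163205	165539	Cytochrome P450
LOC_Os06g01260	167364	174331	Glutathione gamma-glutamylcysteinyltransferase 1
LOC_Os06g01270	178580	178343	Expressed protein
LOC_Os06g01280	180215	181423	Retrotransposon protein
LOC_Os06g01290	182104	184623	Expressed protein
LOC_Os06g01304	185692	191452	Spotted leaf 11
LOC_Os06g01320	195018	208583	Chromodomain, helicase/ATPase, and DNA-binding domain (CHD) proteins
"""

# Parental day-6 germination percentages at 15 degC: (SN265, LTH).
PARENT_MEANS = (15.4, 86.5)

# Mean resequencing depth of the RIL lines and the parental SNP count.
MEAN_RIL_DEPTH = 7.75
N_PARENTAL_SNPS = 123_859


def reference_map_summary() -> pd.DataFrame:
    """Published per-chromosome bin-map characteristics (12 rows)."""
    return pd.read_csv(StringIO(_MAP_SUMMARY_TSV), sep="\t")


def reported_ltg_qtls() -> pd.DataFrame:
    """The eleven published low-temperature germinability QTLs."""
    return pd.read_csv(StringIO(_QTL_TSV), sep="\t")


def qltg6_region_genes() -> pd.DataFrame:
    """Annotated genes of the fine-mapped qLTG6 region, as printed."""
    return pd.read_csv(StringIO(_QLTG6_GENES_TSV), sep="\t")


def rice_chrom_lengths_bp() -> dict[str, int]:
    """Physical chromosome lengths (bp) from the published map summary."""
    s = reference_map_summary()
    return {
        str(c): int(mb * 1e6)
        for c, mb in zip(s["chrom"], s["physical_length_mb"])
    }


def rice_genetic_lengths_cm() -> dict[str, float]:
    """Per-meiosis genetic lengths (cM) used by the simulator.

    The published map totals 2,840.12 cM, roughly twice a consensus rice
    map; linkage maps estimated from noisy low-coverage genotypes are
    inflated by residual genotyping error.  The simulator needs the true
    per-meiosis lengths, so typical rice consensus-map values are used
    instead (total ~1,530 cM).
    """
    consensus = [181.8, 157.0, 166.4, 129.6, 122.3, 124.4,
                 118.6, 121.1, 93.5, 83.8, 117.9, 109.3]
    return {str(i + 1): v for i, v in enumerate(consensus)}
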