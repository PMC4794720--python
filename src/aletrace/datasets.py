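"""Packaged synthetic fixtures.

Everything in this module is SYNTHETIC, generated programmatically and
deterministically.  The flagship fixture is a study-shaped stepwise
thermal-adaptation catalog: 19 intermediate strains sampled at 32, 34,
36 and 38 °C carrying 49 mutational events on a 1.2e7 bp, 16-chromosome
genome, with four distinct point mutations in a CDC25-like driver gene,
one of which (labelled W1416C) is planted on two separate lineages — the
convergence pattern the pipeline is built to detect.  The genealogy the
events are painted on is fully known, so the fixture doubles as an
end-to-end regression oracle.

A small hand-sized expression table and regulator map are provided for
the transcriptome stage.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .parsimony import Node, RootedTree
from .variant_io import (
    EventMatrix,
    GeneIndex,
    MutationEvent,
    StrainRecord,
    assign_genes,
    build_event_matrix,
)

__all__ = [
    "CHROM_LENGTHS",
    "CDC25_LOCUS",
    "synthetic_study_tables",
    "synthetic_study_matrix",
    "synthetic_study_truth",
    "toy_expression_table",
    "toy_regulator_map",
]

# Synthetic 16-chromosome karyotype; lengths sum to exactly 12,000,000 bp.
CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1460607,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}

#: driver gene of the fixture (minus strand, 4758 bp, CDC25-like)
CDC25_LOCUS = ("chrXII", 752751, 757508)

_PARENTAL = "MT8-1"

# The true genealogy: (clade name, members, number of marker events on the
# edge leading to the clade).  Every internal edge carries at least one
# marker so the most-parsimonious tree is unique.
_A = [f"A{i}" for i in range(1, 6)]   # 32 degC isolates
_B = [f"B{i}" for i in range(1, 6)]   # 34 degC
_C = [f"C{i}" for i in range(1, 6)]   # 36 degC
_D = [f"D{i}" for i in range(1, 5)]   # 38 degC

_CLADES: list[tuple[str, list[str], int]] = [
    ("ALL", _A + _B + _C + _D, 1),
    ("G1", _A + ["B1", "B2", "B3"], 1),
    ("A", _A, 1),
    ("A12", ["A1", "A2"], 1),
    ("A345", ["A3", "A4", "A5"], 1),
    ("A45", ["A4", "A5"], 1),
    ("B123", ["B1", "B2", "B3"], 1),
    ("B12", ["B1", "B2"], 1),
    ("G2", ["B4", "B5"] + _C + _D, 1),
    ("B45", ["B4", "B5"], 1),
    ("CD", _C + _D, 1),
    ("C12", ["C1", "C2"], 1),
    ("CDD", ["C3", "C4", "C5"] + _D, 1),
    ("X", ["C4", "C5"] + _D, 1),
    ("C45", ["C4", "C5"], 1),
    ("D", _D, 1),
    ("D12", ["D1", "D2"], 1),
    ("D34", ["D3", "D4"], 1),
]

# private (pendant-edge) passenger counts per strain
_PRIVATES = {
    "A1": 2, "A2": 1, "A3": 2, "A4": 1, "A5": 2,
    "B1": 1, "B2": 2, "B3": 1, "B4": 1, "B5": 2,
    "C1": 2, "C2": 1, "C3": 2, "C4": 1, "C5": 2,
    "D1": 1, "D2": 1, "D3": 1, "D4": 1,
}

# driver-gene events: label, 1-based codon (minus strand), carriers.
# W1416C is planted on TWO separate lineages (a 34 degC pair and the
# 36/38 degC clade) — the same site gained independently twice.
_CDC25_EVENTS = [
    ("T943P", 943, ["B12"]),
    ("G1459C", 1459, ["B4"]),
    ("N1393T", 1393, ["C12"]),
    ("W1416C", 1416, ["B12", "CDD"]),
]

_STAGE_OF = {"A": "32", "B": "34", "C": "36", "D": "38"}


def _codon_position(codon: int) -> int:
    """Middle base of a codon on the minus strand of the driver locus."""
    _, start, end = CDC25_LOCUS
    return end - 3 * codon + 2


def _random_site(
    rng: np.random.Generator, used: set, in_gene_of, used_genes: set
) -> tuple[str, int]:
    chroms = list(CHROM_LENGTHS)
    weights = np.array([CHROM_LENGTHS[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    while True:
        chrom = str(rng.choice(chroms, p=weights))
        pos = int(rng.integers(1, CHROM_LENGTHS[chrom] + 1))
        if (chrom, pos) in used:
            continue
        gene = in_gene_of(chrom, pos)
        if gene == "CDC25":
            continue  # keep the driver gene's hits to the four planted ones
        if gene is not None and gene in used_genes:
            continue  # at most one passenger per background gene
        if gene is not None:
            used_genes.add(gene)
        used.add((chrom, pos))
        return chrom, pos


def _gene_annotation() -> tuple[str, GeneIndex]:
    """GFF3 text + index: the driver gene and 24 background genes."""
    rng = np.random.default_rng(424242)
    genes: dict[str, list[tuple[int, int, str]]] = {c: [] for c in CHROM_LENGTHS}
    genes[CDC25_LOCUS[0]].append((CDC25_LOCUS[1], CDC25_LOCUS[2], "CDC25"))
    i = 1
    while i <= 24:
        chrom = str(rng.choice(list(CHROM_LENGTHS)))
        length = int(rng.integers(900, 3600))
        start = int(rng.integers(1, CHROM_LENGTHS[chrom] - length))
        end = start + length - 1
        if any(s <= end and start <= e for s, e, _ in genes[chrom]):
            continue
        genes[chrom].append((start, end, f"YSN{i:03d}"))
        i += 1
    lines = ["##gff-version 3"]
    for chrom, ln in CHROM_LENGTHS.items():
        lines.append(f"##sequence-region {chrom} 1 {ln}")
    for chrom in CHROM_LENGTHS:
        for start, end, name in sorted(genes[chrom]):
            lines.append(
                f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\t"
                f"ID={name};Name={name}"
            )
    gff = "\n".join(lines) + "\n"
    index = GeneIndex(
        {c: sorted(v) for c, v in genes.items() if v},
        chrom_lengths=CHROM_LENGTHS,
    )
    return gff, index


def synthetic_study_tables() -> tuple[pd.DataFrame, str]:
    """The study-shaped synthetic catalog as (mutation table, GFF3 text).

    19 strains, 49 events; ``read_mutation_table``-compatible columns.
    Deterministic: repeated calls return identical tables.
    """
    gff, index = _gene_annotation()
    rng = np.random.default_rng(12345)
    used: set[tuple[str, int]] = set()
    used_genes: set[str] = set()

    members = {name: mem for name, mem, _ in _CLADES}
    strain_events: dict[str, list[MutationEvent]] = {s: [] for s in _PRIVATES}

    def place(carrier_sets: list[list[str]], event: MutationEvent) -> None:
        for mem in carrier_sets:
            for s in mem:
                if event not in strain_events[s]:
                    strain_events[s].append(event)

    alleles = ["A", "C", "G", "T"]
    # clade markers
    for name, mem, n_markers in _CLADES:
        for _ in range(n_markers):
            chrom, pos = _random_site(rng, used, index.lookup, used_genes)
            ref, alt = rng.choice(alleles, size=2, replace=False)
            place([mem], MutationEvent(chrom=chrom, pos=pos, ref=str(ref), alt=str(alt)))
    # driver events (same site may sit on two lineages: one character)
    for label, codon, carriers in _CDC25_EVENTS:
        pos = _codon_position(codon)
        ref, alt = rng.choice(alleles, size=2, replace=False)
        ev = MutationEvent(
            chrom=CDC25_LOCUS[0], pos=pos, ref=str(ref), alt=str(alt),
            protein_change=label,
        )
        place([members[c] if c in members else [c] for c in carriers], ev)
    # private passengers (mix in a few indels, as real catalogs have)
    for s, k in _PRIVATES.items():
        for j in range(k):
            chrom, pos = _random_site(rng, used, index.lookup, used_genes)
            if rng.random() < 0.15:
                b1, b2 = rng.choice(alleles, size=2, replace=True)
                ref, alt = (str(b1) + str(b2), str(b1)) if rng.random() < 0.5 else (
                    str(b1), str(b1) + str(b2)
                )
            else:
                ref, alt = (str(x) for x in rng.choice(alleles, size=2, replace=False))
            place([[s]], MutationEvent(chrom=chrom, pos=pos, ref=ref, alt=alt))

    rows = []
    for s in sorted(strain_events):
        for ev in strain_events[s]:
            rows.append(
                {
                    "strain": s,
                    "chrom": ev.chrom,
                    "pos": ev.pos,
                    "ref": ev.ref,
                    "alt": ev.alt,
                    "protein_change": ev.protein_change or "",
                    "stage_temp": _STAGE_OF[s[0]],
                }
            )
    table = pd.DataFrame(rows)
    return table, gff


def synthetic_study_matrix() -> tuple[EventMatrix, GeneIndex]:
    """The fixture as a ready-to-analyse (EventMatrix, GeneIndex) pair."""
    table, gff = synthetic_study_tables()
    _, index = _gene_annotation()
    events: dict[str, MutationEvent] = {}
    strain_sets: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        ev = MutationEvent(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            protein_change=row.protein_change or None,
        )
        events.setdefault(ev.event_id, ev)
        strain_sets.setdefault(row.strain, set()).add(ev.event_id)
    annotated = assign_genes(list(events.values()), index)
    strains = [StrainRecord(_PARENTAL, "parental", frozenset())] + [
        StrainRecord(s, _STAGE_OF[s[0]], frozenset(v))
        for s, v in sorted(strain_sets.items())
    ]
    matrix = build_event_matrix(annotated, strains, parental=_PARENTAL)
    return matrix, index


def synthetic_study_truth() -> RootedTree:
    """The genealogy the fixture's events were painted on."""
    clades = [frozenset(mem) for _, mem, _ in _CLADES]

    def build(clade: frozenset[str]) -> Node:
        if len(clade) == 1:
            return Node(next(iter(clade)))
        subs = [c for c in clades if c < clade]
        maximal = [c for c in subs if not any(c < o for o in subs)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        children = sorted(maximal, key=sorted) + [
            frozenset({s}) for s in sorted(clade - covered)
        ]
        node = Node(None)
        for c in children:
            node.add(build(c))
        return node

    root = Node(_PARENTAL)
    root.add(build(frozenset(_A + _B + _C + _D)))
    return RootedTree(root, _PARENTAL)


# ---------------------------------------------------------------------------
# toy transcriptome fixture
# ---------------------------------------------------------------------------

_EXPRESSION_TSV = """\
gene	strain	replicate	fpkm
HSP12	MT8-1	1	10
HSP12	MT8-1	2	14
HSP12	mutA	1	30
HSP12	mutA	2	42
HSP12	mutB	1	20
HSP12	mutB	2	28
HSP104	MT8-1	1	40
HSP104	MT8-1	2	40
HSP104	mutA	1	70
HSP104	mutA	2	70
HSP104	mutB	1	60
HSP104	mutB	2	62
TPS1	MT8-1	1	8
TPS1	MT8-1	2	12
TPS1	mutA	1	18
TPS1	mutA	2	22
TPS1	mutB	1	14
TPS1	mutB	2	18
TPS2	MT8-1	1	20
TPS2	MT8-1	2	20
TPS2	mutA	1	29
TPS2	mutA	2	31
TPS2	mutB	1	30
TPS2	mutB	2	32
PGM2	MT8-1	1	16
PGM2	MT8-1	2	24
PGM2	mutA	1	50
PGM2	mutA	2	50
PGM2	mutB	1	24
PGM2	mutB	2	28
ACT1	MT8-1	1	100
ACT1	MT8-1	2	100
ACT1	mutA	1	101
ACT1	mutA	2	99
ACT1	mutB	1	100
ACT1	mutB	2	102
CDC19	MT8-1	1	60
CDC19	MT8-1	2	60
CDC19	mutA	1	90
CDC19	mutA	2	90
CDC19	mutB	1	58
CDC19	mutB	2	60
GRE1	MT8-1	1	0
GRE1	MT8-1	2	0
GRE1	mutA	1	5
GRE1	mutA	2	5
GRE1	mutB	1	2
GRE1	mutB	2	2
UGP1	MT8-1	1	30
UGP1	MT8-1	2	30
UGP1	mutA	1	46
UGP1	mutA	2	44
UGP1	mutB	1	50
UGP1	mutB	2	48
RPL3	MT8-1	1	200
RPL3	MT8-1	2	200
RPL3	mutA	1	180
RPL3	mutA	2	180
RPL3	mutB	1	210
RPL3	mutB	2	206
"""

_REGULATOR_TSV = """\
regulator	target
Msn2	HSP12
Msn2	HSP104
Msn2	TPS1
Msn2	TPS2
Msn2	PGM2
Msn2	GRE1
Msn4	HSP12
Msn4	TPS1
Msn4	TPS2
Msn4	UGP1
Gis1	GRE1
Gis1	CDC19
Yap1	HSP104
Yap1	RPL3
"""


def toy_expression_table() -> pd.DataFrame:
    """Hand-sized FPKM table: parent MT8-1 + two mutants, two replicates."""
    return pd.read_csv(io.StringIO(_EXPRESSION_TSV), sep="\t")


def toy_regulator_map() -> dict[str, set[str]]:
    """Hand-sized regulator → target map for the attribution stage."""
    out: dict[str, set[str]] = {}
    for line in _REGULATOR_TSV.strip().splitlines()[1:]:
        reg, target = line.split("\t")
        out.setdefault(reg, set()).add(target)
    return out


def write_study_fixture(mutation_path, gff_path) -> None:
    """Write the study-shaped fixture to disk (TSV + GFF3)."""
    table, gff = synthetic_study_tables()
    table.to_csv(mutation_path, sep="\t", index=False)
    with open(gff_path, "w") as fh:
        fh.write(gff)
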