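"""Reading, validation and normalization of mutation catalogs.

The downstream analyses treat every unique genomic change (substitution,
insertion or deletion, identified by chrom/pos/ref/alt) as one binary
presence/absence character scored across strains relative to an
all-reference parental genotype.  This module turns mutation tables
(TSV or minimal VCF), a GFF3 gene annotation and strain metadata into
the :class:`EventMatrix` consumed by the parsimony and convergence
stages.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention);
indel positions are left-anchored on the first affected reference base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationEvent",
    "StrainRecord",
    "GeneIndex",
    "EventMatrix",
    "classify_mtype",
    "read_mutation_table",
    "read_gene_annotation",
    "assign_genes",
    "build_event_matrix",
    "write_matrix",
    "read_matrix",
]

PARENTAL_STAGE = "parental"


class MutationTableError(ValueError):
    """Raised for malformed mutation catalogs."""


def classify_mtype(ref: str, alt: str) -> str:
    """Infer the mutation type from allele lengths (VCF convention).

    len(ref) == len(alt) == 1 -> SNV; longer ref -> deletion; longer
    alt -> insertion.  Equal-length multi-base substitutions are not a
    supported character type and must be decomposed upstream.
    """
    if not ref or not alt:
        raise MutationTableError(f"empty allele in ({ref!r}, {alt!r})")
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) > len(alt):
        return "deletion"
    if len(alt) > len(ref):
        return "insertion"
    raise MutationTableError(
        f"equal-length multi-base substitution ({ref!r}, {alt!r}) is not supported; "
        "decompose it into SNVs upstream"
    )


@dataclass(frozen=True)
class MutationEvent:
    """One unique genomic change — a binary character of the analysis."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mtype: str = ""
    gene_id: str | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MutationTableError(f"position must be >= 1, got {self.pos}")
        expected = classify_mtype(self.ref, self.alt)
        if self.mtype == "":
            object.__setattr__(self, "mtype", expected)
        elif self.mtype != expected:
            raise MutationTableError(
                f"mtype {self.mtype!r} inconsistent with alleles {self.ref}>{self.alt}"
            )

    @property
    def event_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class StrainRecord:
    """A sequenced isolate and the set of events it carries."""

    strain_id: str
    stage_temp: str = ""
    events: frozenset[str] = field(default_factory=frozenset)

    def with_events(self, events: Iterable[str]) -> "StrainRecord":
        return replace(self, events=frozenset(events))


class GeneIndex:
    """Sorted, non-overlapping gene intervals plus the genome length L.

    Intervals are 1-based inclusive.  The index also exposes a single
    concatenated coordinate system over chromosomes (in input order) so
    that uniform position redraws on [1, L] can be mapped back to genes
    vectorially (used by the permutation null).
    """

    def __init__(
        self,
        intervals: Mapping[str, Sequence[tuple[int, int, str]]],
        genome_length: int | None = None,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping gene intervals on {chrom}: "
                        f"{g1} ({s1}-{e1}) and {g2} ({s2}-{e2})"
                    )
            for s, e, g in ivs:
                if s < 1 or e < s:
                    raise ValueError(f"bad interval {g}: {s}-{e}")
            self.intervals[chrom] = list(ivs)

        if chrom_lengths is None:
            chrom_lengths = {
                chrom: (max(e for _, e, _ in ivs) if ivs else 1)
                for chrom, ivs in self.intervals.items()
            }
            if genome_length is None:
                raise ValueError(
                    "genome_length is required when chromosome lengths are "
                    "unknown; pass genome_length= or provide sequence-region "
                    "pragmas in the GFF3"
                )
        self.chrom_lengths = dict(chrom_lengths)
        for chrom, ivs in self.intervals.items():
            if chrom not in self.chrom_lengths:
                self.chrom_lengths[chrom] = max(e for _, e, _ in ivs)
        total = sum(self.chrom_lengths.values())
        self.genome_length = int(genome_length) if genome_length else total
        max_end = max(
            (e for ivs in self.intervals.values() for _, e, _ in ivs), default=0
        )
        if self.genome_length < max_end:
            raise ValueError(
                f"genome_length {self.genome_length} < max interval end {max_end}"
            )

        # concatenated coordinates for vectorized lookups
        self._chrom_order = list(self.chrom_lengths)
        offsets: dict[str, int] = {}
        off = 0
        for chrom in self._chrom_order:
            offsets[chrom] = off
            off += self.chrom_lengths[chrom]
        self._offsets = offsets
        starts, ends, genes = [], [], []
        for chrom in self._chrom_order:
            for s, e, g in self.intervals.get(chrom, []):
                starts.append(offsets[chrom] + s)
                ends.append(offsets[chrom] + e)
                genes.append(g)
        order = np.argsort(starts) if starts else np.array([], dtype=int)
        self._g_starts = np.asarray(starts, dtype=np.int64)[order]
        self._g_ends = np.asarray(ends, dtype=np.int64)[order]
        self.gene_ids = [genes[i] for i in order]
        self.gene_lengths = {
            g: int(e - s + 1)
            for g, s, e in zip(self.gene_ids, self._g_starts, self._g_ends)
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def lookup(self, chrom: str, pos: int) -> str | None:
        """Return the gene containing (chrom, pos), or None."""
        if chrom not in self._offsets:
            return None
        return self.lookup_global(np.asarray([self._offsets[chrom] + pos]))[0]

    def lookup_global(self, gpos: np.ndarray) -> list[str | None]:
        idx = self.lookup_global_idx(gpos)
        return [self.gene_ids[i] if i >= 0 else None for i in idx]

    def lookup_global_idx(self, gpos: np.ndarray) -> np.ndarray:
        """Vectorized: concatenated positions -> gene index (-1 = intergenic)."""
        if self._g_starts.size == 0:
            return np.full(np.shape(gpos), -1, dtype=np.int64)
        j = np.searchsorted(self._g_starts, gpos, side="right") - 1
        jc = np.clip(j, 0, None)
        hit = (j >= 0) & (gpos <= self._g_ends[jc]) & (gpos >= self._g_starts[jc])
        return np.where(hit, jc, -1)

    def global_position(self, chrom: str, pos: int) -> int:
        return self._offsets[chrom] + pos


def read_gene_annotation(path: str | Path, genome_length: int | None = None) -> GeneIndex:
    """Load gene intervals from a GFF3 file into a :class:`GeneIndex`.

    Genome length is taken from ``##sequence-region`` pragmas when
    present, otherwise from ``genome_length``.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            chrom_lengths[parts[1]] = int(parts[3])
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gid])[0]
        intervals.setdefault(feat.seqid, []).append((feat.start, feat.end, name))
    if not chrom_lengths and genome_length is None:
        raise ValueError(
            "GFF3 has no ##sequence-region pragmas; pass genome_length= "
            "(e.g. via the pipeline config) to set L"
        )
    return GeneIndex(
        intervals,
        genome_length=genome_length,
        chrom_lengths=chrom_lengths or None,
    )


def assign_genes(events: Sequence[MutationEvent], index: GeneIndex) -> list[MutationEvent]:
    """Annotate events with the gene whose interval contains them.

    Intergenic events keep ``gene_id=None`` and are retained.  Events on
    chromosomes absent from the index are flagged with a warning and
    left unassigned.  Idempotent and order-independent.
    """
    out = []
    missing: set[str] = set()
    for ev in events:
        if ev.chrom not in index.intervals and ev.chrom not in index.chrom_lengths:
            missing.add(ev.chrom)
            out.append(replace(ev, gene_id=None))
            continue
        out.append(replace(ev, gene_id=index.lookup(ev.chrom, ev.pos)))
    if missing:
        warnings.warn(
            f"chromosomes absent from gene index, events left unassigned: "
            f"{sorted(missing)}"
        )
    return out


def _dedup_events(raw: Iterable[MutationEvent]) -> dict[tuple, MutationEvent]:
    events: dict[tuple, MutationEvent] = {}
    for ev in raw:
        key = ev.site_key
        if key not in events:
            events[key] = ev
        else:
            # keep whichever copy carries annotation
            old = events[key]
            if old.gene_id is None and ev.gene_id is not None:
                events[key] = ev
    return events


def read_mutation_table(
    path: str | Path, dialect: str = "tsv"
) -> tuple[list[MutationEvent], list[StrainRecord]]:
    """Read a per-strain mutation catalog.

    ``tsv`` dialect: tab-separated with header columns
    ``strain, chrom, pos, ref, alt`` and optional
    ``gene, protein_change, stage_temp``; one row per (strain, event).
    ``vcf`` dialect: one sample column per strain; any non-reference,
    non-missing genotype counts as presence.

    Events are deduplicated by (chrom, pos, ref, alt); the same site
    observed in several strains (or several lineages) is ONE character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def _read_tsv(path: Path) -> tuple[list[MutationEvent], list[StrainRecord]]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"strain", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise MutationTableError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    events: dict[tuple, MutationEvent] = {}
    strain_events: dict[str, set[str]] = {}
    strain_stage: dict[str, str] = {}
    seen_pairs: set[tuple[str, str]] = set()
    dup_pairs = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise MutationTableError(
                f"{path}:{i}: non-integer position {row.pos!r}"
            ) from exc
        if pos < 1:
            raise MutationTableError(f"{path}:{i}: position {pos} < 1")
        try:
            ev = MutationEvent(
                chrom=str(row.chrom),
                pos=pos,
                ref=str(row.ref),
                alt=str(row.alt),
                gene_id=getattr(row, "gene", None) if pd.notna(getattr(row, "gene", None)) else None,
                protein_change=getattr(row, "protein_change", None)
                if pd.notna(getattr(row, "protein_change", None))
                else None,
            )
        except MutationTableError as exc:
            raise MutationTableError(f"{path}:{i}: {exc}") from exc
        key = ev.site_key
        if key not in events:
            events[key] = ev
        strain = str(row.strain)
        pair = (strain, events[key].event_id)
        if pair in seen_pairs:
            dup_pairs += 1
        seen_pairs.add(pair)
        strain_events.setdefault(strain, set()).add(events[key].event_id)
        stage = getattr(row, "stage_temp", None)
        if stage is not None and pd.notna(stage):
            strain_stage[strain] = str(stage)
    if dup_pairs:
        warnings.warn(f"{path}: {dup_pairs} duplicate (strain, event) rows collapsed")
    strains = [
        StrainRecord(s, strain_stage.get(s, ""), frozenset(evs))
        for s, evs in strain_events.items()
    ]
    return list(events.values()), strains


def _read_vcf(path: Path) -> tuple[list[MutationEvent], list[StrainRecord]]:
    import pysam

    events: dict[tuple, MutationEvent] = {}
    strain_events: dict[str, set[str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            strain_events[s] = set()
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                ev = MutationEvent(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=str(alt)
                )
                key = ev.site_key
                if key not in events:
                    events[key] = ev
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None:
                        continue
                    if any(a == ai for a in gt if a is not None):
                        strain_events[s].add(events[key].event_id)
    strains = [
        StrainRecord(s, "", frozenset(evs)) for s, evs in strain_events.items()
    ]
    return list(events.values()), strains


class EventMatrix:
    """Binary strain × event presence matrix with a designated parental row.

    The parental strain is the all-reference genotype: its row is all
    zero by construction and it becomes the fixed state-0 root of the
    parsimony analysis.  Columns are ordered deterministically by
    (chrom, pos, ref, alt); all-zero columns are dropped at build time.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        events: Mapping[str, MutationEvent],
        parental: str,
        stage_temps: Mapping[str, str] | None = None,
    ) -> None:
        if parental not in df.index:
            raise ValueError(f"parental strain {parental!r} not in matrix")
        bad = set(np.unique(df.to_numpy())) - {0, 1}
        if bad:
            raise ValueError(f"matrix entries must be 0/1, found {sorted(bad)}")
        if df.loc[parental].to_numpy().any():
            raise ValueError(
                f"parental strain {parental!r} carries events; mutations are "
                "defined relative to the parent"
            )
        if df.index.duplicated().any():
            raise ValueError("duplicate strain_id in matrix")
        self.df = df.astype(np.int8)
        self.events = dict(events)
        self.parental = parental
        self.stage_temps = dict(stage_temps or {})

    @property
    def strain_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxa(self) -> list[str]:
        """Non-parental strains, in matrix order."""
        return [s for s in self.df.index if s != self.parental]

    @property
    def event_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_events(self) -> int:
        return self.df.shape[1]

    def column(self, event_id: str) -> dict[str, int]:
        return {s: int(v) for s, v in self.df[event_id].items()}

    def subset_events(self, event_ids: Sequence[str]) -> "EventMatrix":
        return EventMatrix(
            self.df[list(event_ids)],
            {e: self.events[e] for e in event_ids},
            self.parental,
            self.stage_temps,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EventMatrix({len(self.taxa)} strains + parental, "
            f"{self.n_events} events)"
        )


def build_event_matrix(
    events: Sequence[MutationEvent],
    strains: Sequence[StrainRecord],
    parental: str = "parental",
) -> EventMatrix:
    """Assemble the binary presence matrix from events and strain records.

    The parental strain may be listed among ``strains`` (with an empty
    event set) or just named; either way it becomes the all-zero root
    row.  All-zero event columns are dropped with a warning.
    """
    by_id = {ev.event_id: ev for ev in _dedup_events(events).values()}
    ids = sorted(by_id, key=lambda e: by_id[e].site_key)
    names = [s.strain_id for s in strains]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate strain_id: {dupes}")
    for s in strains:
        if s.strain_id == parental and s.events:
            raise ValueError(
                f"parental strain {parental!r} carries events; mutations are "
                "defined relative to the parent"
            )
        unknown = s.events - set(by_id)
        if unknown:
            raise ValueError(
                f"strain {s.strain_id} references unknown events: {sorted(unknown)}"
            )
    rows = [s for s in strains if s.strain_id != parental]
    index = [parental] + [s.strain_id for s in rows]
    data = np.zeros((len(index), len(ids)), dtype=np.int8)
    for i, s in enumerate(rows, start=1):
        for e in s.events:
            data[i, ids.index(e)] = 1
    df = pd.DataFrame(data, index=index, columns=ids)
    keep = df.to_numpy().sum(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} all-zero event columns: {dropped}")
        df = df.loc[:, keep]
    stage = {s.strain_id: s.stage_temp for s in strains if s.stage_temp}
    stage.setdefault(parental, PARENTAL_STAGE)
    return EventMatrix(df, {e: by_id[e] for e in df.columns}, parental, stage)


def write_matrix(matrix: EventMatrix, path: str | Path) -> None:
    """Serialize as TSV: strains as rows, event_ids as columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# parental={matrix.parental}\n")
        matrix.df.to_csv(fh, sep="\t", index_label="strain")


def read_matrix(path: str | Path) -> EventMatrix:
    """Read back a matrix written by :func:`write_matrix` (bit-exact)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# parental="):
            raise MutationTableError(f"{path}: missing '# parental=' header line")
        parental = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col="strain")
    events = {}
    for eid in df.columns:
        chrom, pos, change = eid.split(":")
        ref, alt = change.split(">")
        events[eid] = MutationEvent(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
    return EventMatrix(df, events, parental)
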