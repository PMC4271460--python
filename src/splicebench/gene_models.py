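"""Gene models, counting-unit flattening and splice-event classification.

A gene model is a set of transcripts, each an ordered list of exon
intervals (1-based, inclusive, GFF3 convention).  Flattening a gene cuts
the union of its exons at every splice boundary seen in any transcript,
producing disjoint exonic *counting bins*, and adds one *junction* unit
per distinct intron.  Counting units are the granularity at which
count-based differential-splicing statistics operate.

Pairwise comparison of two transcripts yields local splice events,
classified into the simple types — skipped exon (SE), intron retention
(IR), alternative 5'/3' splice site (A5SS/A3SS, strand-aware), mutually
exclusive exons (MXE) — or ``complex`` for anything else.  Differences
confined to the outer transcript ends (alternative transcription start
or termination) are not splicing and are ignored.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import gffutils
import numpy as np

__all__ = [
    "Transcript",
    "GeneModel",
    "CountingUnit",
    "SpliceEvent",
    "GeneASClass",
    "AnnotationError",
    "SIMPLE_CLASSES",
    "parse_annotation",
    "write_gff3",
    "write_gtf",
    "write_units_bed",
    "write_events_tsv",
    "flatten_gene",
    "extract_events",
    "classify_gene",
    "make_incomplete_annotation",
    "synth_annotation",
]


class AnnotationError(ValueError):
    """Malformed annotation input or inconsistent gene structure."""


Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    """One mRNA: an ordered tuple of non-overlapping exon intervals."""

    transcript_id: str
    exons: tuple[Interval, ...]

    def __post_init__(self):
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        for (s, e) in exons:
            if s > e:
                raise AnnotationError(f"{self.transcript_id}: bad exon [{s},{e}]")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping/abutting exons near {e1}"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals [donor_end+1, acceptor_start-1], exclusive of exons."""
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        ids = [t.transcript_id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            raise AnnotationError(f"{self.gene_id}: duplicate transcript ids")

    @property
    def span(self) -> Interval:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class CountingUnit:
    """A disjoint exonic bin or a splice junction of one gene.

    For ``exonic_bin`` the interval is [start, end] (1-based inclusive);
    for ``junction`` it is (donor_end, acceptor_start) — the last exonic
    base before the intron and the first exonic base after it.
    """

    unit_id: str
    gene_id: str
    kind: str  # "exonic_bin" | "junction"
    start: int
    end: int
    effective_length: float
    member_transcripts: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("exonic_bin", "junction"):
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if self.effective_length <= 0:
            raise ValueError(f"{self.unit_id}: effective_length must be > 0")


SIMPLE_EVENT_TYPES = ("SE", "IR", "A3SS", "A5SS", "MXE")


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    type: str  # SE | IR | A3SS | A5SS | MXE | complex
    region: Interval  # genomic span of the differing region
    inclusion_units: frozenset[str]
    exclusion_units: frozenset[str]
    transcripts: tuple[str, str]  # (inclusion-form transcript, the other)

    def __post_init__(self):
        if self.inclusion_units & self.exclusion_units:
            raise ValueError(f"{self.event_id}: inclusion/exclusion units overlap")
        if self.type in SIMPLE_EVENT_TYPES and not (
            self.inclusion_units and self.exclusion_units
        ):
            raise ValueError(
                f"{self.event_id}: simple event must have units on both sides"
            )


SIMPLE_CLASSES = ("SE", "IR", "A3A5SS")
ALL_CLASSES = ("SE", "IR", "A3A5SS", "MXE", "complex", "multi_event", "single_isoform")


@dataclass(frozen=True)
class GeneASClass:
    gene_id: str
    n_transcripts: int
    as_class: str

    def __post_init__(self):
        if self.as_class not in ALL_CLASSES:
            raise ValueError(f"unknown AS class {self.as_class!r}")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _precheck_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(">"):
                if line.startswith(">"):  # FASTA tail in some GFF3 dumps
                    return
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"parse error at line {lineno}: expected 9 tab-separated "
                    f"columns, got {line.count(chr(9)) + 1}"
                )


def parse_annotation(path: str, dialect: str = "GFF3") -> list[GeneModel]:
    """Read gene models from a GFF3 or GTF file.

    Requires gene / mRNA (or transcript) / exon features with parent links
    (GFF3) or ``gene_id``/``transcript_id`` attributes (GTF).  Coordinates
    are kept 1-based inclusive.
    """
    if dialect not in ("GFF3", "GTF"):
        raise ValueError(f"dialect must be GFF3 or GTF, got {dialect!r}")
    _precheck_lines(path)
    kwargs = dict(
        dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    if dialect == "GTF":
        kwargs.update(
            disable_infer_genes=False,
            disable_infer_transcripts=False,
        )
    db = gffutils.create_db(path, **kwargs)

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for t in db.children(g, featuretype=_TRANSCRIPT_TYPES, order_by="start"):
            exons = [(e.start, e.end) for e in db.children(t, featuretype="exon")]
            if not exons:
                raise AnnotationError(
                    f"structural error: transcript {t.id} of gene {g.id} has no exons"
                )
            transcripts.append(Transcript(t.id, tuple(sorted(exons))))
        if not transcripts:
            continue  # gene with no mRNA children (e.g. ncRNA-only loci)
        strand = g.strand if g.strand in ("+", "-") else "+"
        genes.append(GeneModel(g.id, g.seqid, strand, transcripts))
    if dialect == "GFF3":
        for e in db.features_of_type("exon"):
            if not any(True for _ in db.parents(e, featuretype=_TRANSCRIPT_TYPES)):
                raise AnnotationError(
                    f"structural error: exon at {e.seqid}:{e.start}-{e.end} "
                    "has no parent transcript"
                )
    return genes


def write_gff3(genes: list[GeneModel], path: str, header_comment: str | None = None):
    """Write gene models as GFF3 (1-based inclusive, as stored)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsplicebench\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tsplicebench\tmRNA\t{t.start}\t{t.end}\t.\t"
                    f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for (xs, xe) in t.exons:
                    fh.write(
                        f"{g.chrom}\tsplicebench\texon\t{xs}\t{xe}\t.\t{g.strand}"
                        f"\t.\tParent={t.transcript_id}\n"
                    )


def write_gtf(genes: list[GeneModel], path: str, header_comment: str | None = None):
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for g in genes:
            for t in g.transcripts:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{g.chrom}\tsplicebench\ttranscript\t{t.start}\t{t.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for (xs, xe) in t.exons:
                    fh.write(
                        f"{g.chrom}\tsplicebench\texon\t{xs}\t{xe}\t.\t{g.strand}"
                        f"\t.\t{attrs}\n"
                    )


def write_units_bed(units: list[CountingUnit], chrom_by_gene: dict[str, str], path: str):
    """Counting units as BED (0-based half-open at the boundary)."""
    with open(path, "w") as fh:
        for u in units:
            chrom = chrom_by_gene[u.gene_id]
            fh.write(f"{chrom}\t{u.start - 1}\t{u.end}\t{u.unit_id}\t0\t.\n")


def write_events_tsv(events: list[SpliceEvent], path: str):
    with open(path, "w") as fh:
        fh.write("event_id\tgene_id\ttype\tstart\tend\tinclusion_units\t"
                 "exclusion_units\n")
        for ev in events:
            fh.write(
                f"{ev.event_id}\t{ev.gene_id}\t{ev.type}\t{ev.region[0]}\t"
                f"{ev.region[1]}\t{','.join(sorted(ev.inclusion_units))}\t"
                f"{','.join(sorted(ev.exclusion_units))}\n"
            )


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Interval set a minus interval set b."""
    out = []
    b = _merge_intervals(list(b))
    for s, e in a:
        cur = s
        for bs, be in b:
            if be < cur or bs > e:
                continue
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


def _covers(t: Transcript, iv: Interval) -> bool:
    return any(xs <= iv[0] and iv[1] <= xe for xs, xe in t.exons)


def _is_intronic(t: Transcript, iv: Interval) -> bool:
    return not any(xs <= iv[1] and iv[0] <= xe for xs, xe in t.exons)


def _is_full_exon(t: Transcript, iv: Interval) -> bool:
    return iv in t.exons


def _is_internal_exon(t: Transcript, iv: Interval) -> bool:
    return iv in t.exons[1:-1]


def _is_full_intron(t: Transcript, iv: Interval) -> bool:
    return iv in t.introns


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


def flatten_gene(gene: GeneModel, read_length: int = 100) -> list[CountingUnit]:
    """Flatten a gene into disjoint exonic bins plus junction units.

    Bins are the maximal intervals between consecutive distinct exon
    boundaries of any transcript, restricted to the exon union; one
    junction unit is emitted per distinct intron.  Exonic effective
    length is the bin length; junction effective length is
    ``read_length - 1`` (the number of read start positions that span
    the junction).
    """
    if read_length < 2:
        raise ValueError(f"read_length must be >= 2, got {read_length}")
    if not gene.transcripts:
        raise AnnotationError(f"{gene.gene_id}: gene has no transcripts")

    bounds: set[int] = set()
    for t in gene.transcripts:
        for s, e in t.exons:
            bounds.add(s)
            bounds.add(e + 1)  # half-open cut point
    cuts = sorted(bounds)

    units: list[CountingUnit] = []
    for c1, c2 in zip(cuts, cuts[1:]):
        iv = (c1, c2 - 1)
        members = frozenset(
            t.transcript_id for t in gene.transcripts if _covers(t, iv)
        )
        if not members:
            continue  # intronic in every transcript
        units.append(
            CountingUnit(
                unit_id=f"{gene.gene_id}:E{iv[0]}-{iv[1]}",
                gene_id=gene.gene_id,
                kind="exonic_bin",
                start=iv[0],
                end=iv[1],
                effective_length=float(iv[1] - iv[0] + 1),
                member_transcripts=members,
            )
        )

    introns: dict[Interval, set[str]] = {}
    for t in gene.transcripts:
        for (_, e1), (s2, _) in zip(t.exons, t.exons[1:]):
            introns.setdefault((e1, s2), set()).add(t.transcript_id)
    for (donor_end, acceptor_start), members in sorted(introns.items()):
        units.append(
            CountingUnit(
                unit_id=f"{gene.gene_id}:J{donor_end}-{acceptor_start}",
                gene_id=gene.gene_id,
                kind="junction",
                start=donor_end,
                end=acceptor_start,
                effective_length=float(read_length - 1),
                member_transcripts=frozenset(members),
            )
        )
    return units


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------


def _local_regions(
    d1: list[Interval], d2: list[Interval], shared: list[Interval]
) -> list[list[tuple[Interval, int]]]:
    """Group differing intervals into local regions.

    Two differing intervals belong to the same region unless a shared
    exonic segment lies between them.
    """
    tagged = sorted([(iv, 1) for iv in d1] + [(iv, 2) for iv in d2])
    regions: list[list[tuple[Interval, int]]] = []
    for item in tagged:
        if regions:
            prev_end = max(iv[1] for iv, _ in regions[-1])
            sep = any(prev_end < s and e < item[0][0] for s, e in shared)
            if not sep:
                regions[-1].append(item)
                continue
        regions.append([item])
    return regions


def _classify_region(
    t1: Transcript, t2: Transcript, region: list[tuple[Interval, int]], strand: str
) -> tuple[str, str]:
    """Return (event type, inclusion owner: 't1'|'t2') for one local region."""
    d1 = [iv for iv, who in region if who == 1]
    d2 = [iv for iv, who in region if who == 2]

    def _one_sided(iv: Interval, owner: Transcript, other: Transcript):
        # Skipped exon: iv is a full internal exon of owner, intronic in other
        if _is_full_exon(owner, iv) and _is_intronic(other, iv):
            if _is_internal_exon(owner, iv):
                return "SE"
            return None
        # Intron retention: iv is exactly an intron of other, fully exonic in owner
        if _is_full_intron(other, iv) and _covers(owner, iv):
            return "IR"
        # Alternative donor/acceptor: iv extends an exon of owner past a
        # boundary shared with other on exactly one side
        left_anchor = _covers(owner, (iv[0] - 1, iv[0] - 1)) and _covers(
            other, (iv[0] - 1, iv[0] - 1)
        )
        right_anchor = _covers(owner, (iv[1] + 1, iv[1] + 1)) and _covers(
            other, (iv[1] + 1, iv[1] + 1)
        )
        if left_anchor and not right_anchor and _is_intronic(other, iv):
            # differing boundary is the right (downstream) exon end:
            # donor site on '+', acceptor on '-'
            if any(xe == iv[1] for _, xe in owner.exons):
                return "A5SS" if strand == "+" else "A3SS"
        if right_anchor and not left_anchor and _is_intronic(other, iv):
            if any(xs == iv[0] for xs, _ in owner.exons):
                return "A3SS" if strand == "+" else "A5SS"
        return None

    if len(d1) == 1 and not d2:
        kind = _one_sided(d1[0], t1, t2)
        if kind:
            return kind, "t1"
    if len(d2) == 1 and not d1:
        kind = _one_sided(d2[0], t2, t1)
        if kind:
            return kind, "t2"
    if len(d1) == 1 and len(d2) == 1:
        a, b = d1[0], d2[0]
        if (
            a[1] < b[0] or b[1] < a[0]
        ) and (
            _is_full_exon(t1, a)
            and _is_internal_exon(t1, a)
            and _is_intronic(t2, a)
            and _is_full_exon(t2, b)
            and _is_internal_exon(t2, b)
            and _is_intronic(t1, b)
        ):
            return "MXE", "t1"
    return "complex", "t1"


def extract_events(
    t1: Transcript,
    t2: Transcript,
    strand: str,
    gene_id: str = "gene",
    read_length: int = 100,
) -> list[SpliceEvent]:
    """Compare two transcripts of one gene and classify their local
    splicing differences.

    Differences confined to the outer transcript ends (upstream of the
    first shared exonic base or downstream of the last) reflect
    alternative transcription start/termination, not splicing, and are
    ignored.  Identical exon structures yield an empty list.
    """
    if strand not in ("+", "-"):
        raise AnnotationError(f"strand must be '+' or '-', got {strand!r}")
    ex1, ex2 = list(t1.exons), list(t2.exons)
    if ex1 == ex2:
        return []
    shared = _intersect(ex1, ex2)
    if not shared:
        # no common exonic sequence: a single opaque complex difference
        span = (min(t1.start, t2.start), max(t1.end, t2.end))
        return [
            SpliceEvent(
                event_id=f"{gene_id}:{t1.transcript_id}|{t2.transcript_id}:1",
                gene_id=gene_id,
                type="complex",
                region=span,
                inclusion_units=frozenset(),
                exclusion_units=frozenset(),
                transcripts=(t1.transcript_id, t2.transcript_id),
            )
        ]
    lo, hi = shared[0][0], shared[-1][1]
    clip = [(lo, hi)]
    d1 = _intersect(_subtract(ex1, ex2), clip)
    d2 = _intersect(_subtract(ex2, ex1), clip)
    if not d1 and not d2:
        return []  # TSS/TES-only differences

    # counting units of the two-transcript mini-gene, for event membership
    mini = GeneModel(gene_id, "chr", strand, [t1, t2])
    units = flatten_gene(mini, read_length=read_length)

    events: list[SpliceEvent] = []
    for k, region in enumerate(_local_regions(d1, d2, shared), start=1):
        kind, owner = _classify_region(t1, t2, region, strand)
        rs = min(iv[0] for iv, _ in region)
        re_ = max(iv[1] for iv, _ in region)
        inc_t, exc_t = (
            (t1.transcript_id, t2.transcript_id)
            if owner == "t1"
            else (t2.transcript_id, t1.transcript_id)
        )
        inc_units, exc_units = set(), set()
        for u in units:
            if u.end < rs - 1 or u.start > re_ + 1:
                continue
            if u.member_transcripts == {inc_t}:
                inc_units.add(u.unit_id)
            elif u.member_transcripts == {exc_t}:
                exc_units.add(u.unit_id)
        events.append(
            SpliceEvent(
                event_id=f"{gene_id}:{t1.transcript_id}|{t2.transcript_id}:{k}",
                gene_id=gene_id,
                type=kind,
                region=(rs, re_),
                inclusion_units=frozenset(inc_units),
                exclusion_units=frozenset(exc_units),
                transcripts=(inc_t, exc_t),
            )
        )
    return events


def classify_gene(gene: GeneModel, read_length: int = 100) -> GeneASClass:
    """Assign a gene-level alternative-splicing class.

    Two-transcript genes with exactly one simple event get that event's
    type, with A3SS and A5SS merged into the joint A3A5SS class.  MXE is
    kept as its own class here but callers building the three-class
    partition group it with ``complex``.  Any complex event dominates;
    several distinct events make the gene ``multi_event``.  Genes with
    more than two transcripts are classified from all pairwise
    comparisons and are simple only when every differing pair agrees on
    one and the same event.
    """
    n = gene.n_transcripts
    if n == 1:
        return GeneASClass(gene.gene_id, 1, "single_isoform")
    all_events: list[SpliceEvent] = []
    per_pair_counts: list[int] = []
    for ta, tb in itertools.combinations(gene.transcripts, 2):
        evs = extract_events(ta, tb, gene.strand, gene.gene_id, read_length)
        all_events.extend(evs)
        per_pair_counts.append(len(evs))
    if not all_events:
        return GeneASClass(gene.gene_id, n, "single_isoform")
    if any(e.type == "complex" for e in all_events):
        return GeneASClass(gene.gene_id, n, "complex")
    signatures = {(e.type, e.region) for e in all_events}
    if len(signatures) == 1 and max(per_pair_counts) == 1:
        kind = all_events[0].type
        if kind in ("A3SS", "A5SS"):
            kind = "A3A5SS"
        return GeneASClass(gene.gene_id, n, kind)
    return GeneASClass(gene.gene_id, n, "multi_event")


# ---------------------------------------------------------------------------
# annotation transforms and synthesis
# ---------------------------------------------------------------------------


def make_incomplete_annotation(genes: list[GeneModel], truth) -> list[GeneModel]:
    """Drop the designated alternative transcript of every true-AS gene.

    Emulates an annotation that predates discovery of the alternative
    isoforms: detectors running on the returned models must find the
    simulated events as *novel* splicing.  ``truth`` is a TruthTable
    DataFrame with columns gene_id / is_true_as / alt_transcript_id.
    """
    alt = {
        r.gene_id: r.alt_transcript_id
        for r in truth.itertuples()
        if r.is_true_as
    }
    out: list[GeneModel] = []
    for g in genes:
        if g.gene_id not in alt:
            out.append(copy.deepcopy(g))
            continue
        tid = alt[g.gene_id]
        kept = [t for t in g.transcripts if t.transcript_id != tid]
        if len(kept) == len(g.transcripts):
            raise AnnotationError(
                f"{g.gene_id}: alternative transcript {tid!r} not in gene model"
            )
        if not kept:
            raise AnnotationError(f"{g.gene_id}: removal would leave no transcript")
        out.append(GeneModel(g.gene_id, g.chrom, g.strand, kept))
    return out


_DEFAULT_LENGTHS = {
    # plant-like geometry: short exons, short introns
    "exon": (60, 300),
    "intron": (70, 400),
    "alt_shift": (10, 60),  # donor/acceptor shift for A3A5SS events
    "intergenic": (200, 1000),
}


def _build_class_gene(
    as_class: str, gene_id: str, chrom: str, strand: str, cursor: int, rng, lp
) -> tuple[GeneModel, int]:
    """Construct one gene realizing ``as_class``; returns (gene, next cursor)."""

    def L(key):
        lo, hi = lp[key]
        return int(rng.integers(lo, hi + 1))

    def exon_chain(n):
        ivs = []
        pos = cursor
        for i in range(n):
            e = L("exon")
            ivs.append((pos, pos + e - 1))
            pos += e + (L("intron") if i < n - 1 else 0)
        return ivs, pos

    if as_class == "single_isoform":
        ex, end = exon_chain(2)
        ts = [Transcript(f"{gene_id}.1", tuple(ex))]
    elif as_class == "SE":
        ex, end = exon_chain(3)
        ts = [
            Transcript(f"{gene_id}.1", tuple(ex)),
            Transcript(f"{gene_id}.2", (ex[0], ex[2])),
        ]
    elif as_class == "IR":
        ex, end = exon_chain(2)
        ts = [
            Transcript(f"{gene_id}.1", tuple(ex)),
            Transcript(f"{gene_id}.2", ((ex[0][0], ex[1][1]),)),
        ]
    elif as_class == "A3A5SS":
        ex, end = exon_chain(2)
        shift = min(L("alt_shift"), ex[1][0] - ex[0][1] - 2)
        if rng.integers(2):  # move the upstream exon's right end
            ex2 = [(ex[0][0], ex[0][1] + shift), ex[1]]
        else:  # move the downstream exon's left end
            ex2 = [ex[0], (ex[1][0] - shift, ex[1][1])]
        ts = [
            Transcript(f"{gene_id}.1", tuple(ex)),
            Transcript(f"{gene_id}.2", tuple(ex2)),
        ]
    elif as_class == "MXE":
        ex, end = exon_chain(4)
        ts = [
            Transcript(f"{gene_id}.1", (ex[0], ex[1], ex[3])),
            Transcript(f"{gene_id}.2", (ex[0], ex[2], ex[3])),
        ]
    elif as_class == "complex":
        # exon skip combined with an alternative donor in one local region
        ex, end = exon_chain(3)
        shift = min(L("alt_shift"), ex[1][0] - ex[0][1] - 2)
        ts = [
            Transcript(f"{gene_id}.1", tuple(ex)),
            Transcript(f"{gene_id}.2", ((ex[0][0], ex[0][1] + shift), ex[2])),
        ]
    elif as_class == "multi_event":
        # two separate skipped exons flanking a shared middle exon
        ex, end = exon_chain(5)
        ts = [
            Transcript(f"{gene_id}.1", tuple(ex)),
            Transcript(f"{gene_id}.2", (ex[0], ex[2], ex[4])),
        ]
    else:
        raise ValueError(f"cannot synthesize class {as_class!r}")
    gene = GeneModel(gene_id, chrom, strand, ts)
    return gene, end + L("intergenic")


def _allocate(n: int, mix: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of n genes to classes."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    classes = list(mix)
    exact = [n * mix[c] for c in classes]
    counts = [int(x) for x in exact]
    rem = n - sum(counts)
    order = sorted(range(len(classes)), key=lambda i: exact[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    labels = []
    for c, k in zip(classes, counts):
        labels.extend([c] * k)
    return labels


def synth_annotation(
    n_genes: int,
    class_mix: dict[str, float] | None = None,
    length_params: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    chrom: str = "synthchr1",
    verify: bool = True,
) -> list[GeneModel]:
    """Generate a synthetic annotation of non-overlapping genes.

    Each gene is built to realize its assigned AS class (verified via
    :func:`classify_gene` unless ``verify=False``).  Class counts follow a
    deterministic largest-remainder allocation, so the requested mix is
    met exactly; only lengths and strands are random.  Fully
    deterministic under ``seed``.

    The default mix reflects the splicing landscape of a compact plant
    genome, where intron retention dominates and exon skipping is rare.
    """
    if class_mix is None:
        class_mix = {
            "IR": 0.40,
            "A3A5SS": 0.30,
            "SE": 0.05,
            "complex": 0.15,
            "multi_event": 0.10,
        }
    lp = dict(_DEFAULT_LENGTHS)
    if length_params:
        lp.update(length_params)
    for key, (lo, hi) in lp.items():
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible length range for {key!r}: ({lo}, {hi})")
    if lp["exon"][0] < 30:
        raise ValueError("minimum exon length must be >= 30 nt")

    rng = np.random.default_rng(seed)
    labels = _allocate(n_genes, class_mix)
    genes: list[GeneModel] = []
    cursor = 1 + int(rng.integers(*lp["intergenic"]))
    width = len(str(max(n_genes, 1)))
    for i, cls in enumerate(labels, start=1):
        strand = "+" if rng.integers(2) else "-"
        gid = f"SYNT{i:0{width}d}"
        gene, cursor = _build_class_gene(cls, gid, chrom, strand, cursor, rng, lp)
        if verify:
            got = classify_gene(gene).as_class
            if got != cls:
                raise AnnotationError(
                    f"generation error: {gid} built for {cls} classifies as {got}"
                )
        genes.append(gene)
    return genes
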