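"""Custom OR annotation construction: hit filtering and GTF merging.

Olfactory receptor repertoires are poorly covered by base genome
annotations, so curated OR coding sequences are aligned back to the genome
and stitched into the annotation: alignment hits below 95% identity are
discarded, receptors hitting more than one locus are removed, overlapping
receptor hits are resolved to a single best hit, and the survivors replace
any base annotation records they overlap (or are appended when intergenic).

Coordinates are 0-based half-open internally (PSL convention); GTF I/O
converts to 1-based inclusive at the boundary. OR coding regions are
modelled as single intervals, matching the intronless-CDS convention of OR
catalogs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentHit",
    "GtfRecord",
    "MergeReport",
    "compute_identity",
    "filter_identity",
    "drop_multimappers",
    "resolve_or_overlaps",
    "merge_annotations",
    "build_custom_annotation",
    "read_hits_tsv",
    "read_gtf",
    "write_gtf",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One OR-to-genome alignment record (0-based half-open coordinates)."""

    or_id: str
    chrom: str
    start: int
    end: int
    strand: str
    matches: int
    mismatches: int
    query_gap_bases: int = 0
    target_gap_bases: int = 0
    query_length: int = 0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.or_id}: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.or_id}: strand must be '+' or '-'")
        if self.query_length and self.matches + self.mismatches > self.query_length:
            raise ValueError(f"{self.or_id}: matches + mismatches exceed query length")


@dataclass(frozen=True)
class GtfRecord:
    """One GTF line (1-based inclusive coordinates)."""

    seqname: str
    source: str
    feature: str
    start: int
    end: int
    strand: str
    attributes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"need 1 <= start <= end, got [{self.start}, {self.end}]")
        if not self.gene_id:
            raise ValueError("attributes must carry a nonempty gene_id")

    @property
    def gene_id(self) -> str:
        for k, v in self.attributes:
            if k == "gene_id":
                return v
        return ""


@dataclass
class MergeReport:
    """Inventory of what happened to every input hit during merging."""

    n_input_hits: int = 0
    n_dropped_low_identity: int = 0
    n_dropped_multimap: int = 0
    n_dropped_overlap: int = 0
    n_replaced_annotations: int = 0
    n_appended: int = 0

    @property
    def n_survivors(self) -> int:
        return (
            self.n_input_hits
            - self.n_dropped_low_identity
            - self.n_dropped_multimap
            - self.n_dropped_overlap
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def compute_identity(hit: AlignmentHit) -> float:
    """Percent identity: 100 * matches / (matches + mismatches + query_gap_bases)."""
    denom = hit.matches + hit.mismatches + hit.query_gap_bases
    if denom <= 0:
        raise ValueError(f"{hit.or_id}: identity undefined (no aligned bases)")
    return 100.0 * hit.matches / denom


def filter_identity(
    hits: list[AlignmentHit], threshold: float = 95.0
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Split hits into (kept, dropped); hits with identity < threshold are dropped."""
    kept, dropped = [], []
    for h in hits:
        (kept if compute_identity(h) >= threshold else dropped).append(h)
    return kept, dropped


def drop_multimappers(
    hits: list[AlignmentHit],
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Remove every hit of any OR that maps to more than one retained locus."""
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.or_id] = counts.get(h.or_id, 0) + 1
    kept = [h for h in hits if counts[h.or_id] == 1]
    dropped = [h for h in hits if counts[h.or_id] > 1]
    return kept, dropped


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # half-open intervals share >= 1 base
    return a_start < b_end and b_start < a_end


def resolve_or_overlaps(
    hits: list[AlignmentHit],
    seed: int,
    *,
    strand_aware: bool = False,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Keep a best hit among overlapping OR hits; drop the hits it overlaps.

    Within each overlap-connected component (same chromosome, >= 1 shared
    base; strand-agnostic unless ``strand_aware``) the hit with the highest
    identity is kept and every remaining hit overlapping it is discarded;
    the rule is then reapplied to what is left of the component, so a chain
    A–B–C with A best keeps both A and C when they do not overlap each
    other. Exact identity ties are broken by a seeded uniform choice, making
    the output reproducible for a given seed and independent of the seed
    whenever no ties occur.
    """
    rng = np.random.default_rng(seed)
    kept: list[AlignmentHit] = []
    dropped: list[AlignmentHit] = []

    def same_group(a: AlignmentHit, b: AlignmentHit) -> bool:
        if a.chrom != b.chrom:
            return False
        if strand_aware and a.strand != b.strand:
            return False
        return _overlaps(a.start, a.end, b.start, b.end)

    # connected components via union of overlapping intervals, in genomic order
    order = sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.or_id))
    unassigned = list(order)
    while unassigned:
        comp = [unassigned.pop(0)]
        changed = True
        while changed:
            changed = False
            for h in list(unassigned):
                if any(same_group(h, c) for c in comp):
                    comp.append(h)
                    unassigned.remove(h)
                    changed = True
        # iteratively keep the component best, discard its overlappers
        remaining = comp
        while remaining:
            best_identity = max(compute_identity(h) for h in remaining)
            tied = sorted(
                (h for h in remaining if compute_identity(h) == best_identity),
                key=lambda h: h.or_id,
            )
            winner = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
            kept.append(winner)
            nxt = []
            for h in remaining:
                if h is winner:
                    continue
                if same_group(h, winner):
                    dropped.append(h)
                else:
                    nxt.append(h)
            remaining = nxt
    kept.sort(key=lambda h: (h.chrom, h.start, h.end, h.or_id))
    return kept, dropped


def hit_to_gtf(hit: AlignmentHit, source: str = "olfatlas", feature: str = "exon") -> GtfRecord:
    """Convert a half-open hit to a 1-based inclusive GTF record."""
    return GtfRecord(
        seqname=hit.chrom,
        source=source,
        feature=feature,
        start=hit.start + 1,
        end=hit.end,
        strand=hit.strand,
        attributes=(("gene_id", hit.or_id), ("transcript_id", hit.or_id)),
    )


def merge_annotations(
    base: list[GtfRecord],
    survivors: list[AlignmentHit],
    report: MergeReport | None = None,
) -> tuple[list[GtfRecord], MergeReport]:
    """Replace overlapped base records with OR records; append the rest.

    Any base record whose interval overlaps a surviving OR hit on the same
    chromosome (strand-agnostic, any feature type) is removed and the OR
    record takes its place; OR hits overlapping nothing are appended as new
    records. Output is sorted by (seqname, start). The report accumulates
    ``n_replaced_annotations`` (base records removed) and ``n_appended``.
    """
    report = report or MergeReport(n_input_hits=len(survivors))
    replaced_idx: set[int] = set()
    or_records: list[GtfRecord] = []
    for hit in survivors:
        overlapped = [
            i
            for i, rec in enumerate(base)
            if rec.seqname == hit.chrom
            and _overlaps(hit.start, hit.end, rec.start - 1, rec.end)
        ]
        rec = hit_to_gtf(hit)
        if overlapped:
            new = [i for i in overlapped if i not in replaced_idx]
            replaced_idx.update(new)
            report.n_replaced_annotations += len(new)
        else:
            report.n_appended += 1
        or_records.append(rec)
    merged = [rec for i, rec in enumerate(base) if i not in replaced_idx]
    merged.extend(or_records)
    merged.sort(key=lambda r: (r.seqname, r.start, r.end, r.gene_id))
    return merged, report


def build_custom_annotation(
    hits: list[AlignmentHit],
    base: list[GtfRecord],
    *,
    min_identity: float = 95.0,
    seed: int = 7,
    strand_aware: bool = False,
) -> tuple[list[GtfRecord], MergeReport]:
    """Full pipeline: identity filter -> multimapper removal -> overlap resolution -> merge."""
    report = MergeReport(n_input_hits=len(hits))
    kept, low = filter_identity(hits, min_identity)
    report.n_dropped_low_identity = len(low)
    kept, multi = drop_multimappers(kept)
    report.n_dropped_multimap = len(multi)
    kept, overl = resolve_or_overlaps(kept, seed, strand_aware=strand_aware)
    report.n_dropped_overlap = len(overl)
    merged, report = merge_annotations(base, kept, report)
    return merged, report


# ---------------------------------------------------------------------------
# I/O: PSL-derived hit TSV and 9-column GTF

_HIT_COLUMNS = [
    "or_id", "chrom", "start", "end", "strand",
    "matches", "mismatches", "query_gap_bases", "target_gap_bases", "query_length",
]


def read_hits_tsv(path: str | Path) -> list[AlignmentHit]:
    """Read a PSL-derived TSV of alignment hits (documented column map)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return [
        AlignmentHit(
            or_id=str(r.or_id), chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            strand=str(r.strand), matches=int(r.matches), mismatches=int(r.mismatches),
            query_gap_bases=int(r.query_gap_bases), target_gap_bases=int(r.target_gap_bases),
            query_length=int(r.query_length),
        )
        for r in df.itertuples(index=False)
    ]


def write_hits_tsv(hits: list[AlignmentHit], path: str | Path) -> None:
    pd.DataFrame([asdict(h) for h in hits], columns=_HIT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _parse_attributes(text: str, lineno: int) -> tuple[tuple[str, str], ...]:
    attrs = []
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ValueError(f"malformed GTF attributes at line {lineno}: {chunk!r}")
        attrs.append((key, value.strip().strip('"')))
    return tuple(attrs)


def read_gtf(path: str | Path) -> list[GtfRecord]:
    """Read tab-separated 9-column GTF with `key "value";` attributes."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF record at line {lineno}: expected 9 fields, got {len(fields)}")
        seqname, source, feature, start, end, _score, strand, _frame, attrs = fields
        records.append(
            GtfRecord(
                seqname=seqname, source=source, feature=feature,
                start=int(start), end=int(end), strand=strand,
                attributes=_parse_attributes(attrs, lineno),
            )
        )
    return records


def write_gtf(records: list[GtfRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        attrs = " ".join(f'{k} "{v}";' for k, v in r.attributes)
        lines.append(
            "\t".join([r.seqname, r.source, r.feature, str(r.start), str(r.end), ".", r.strand, ".", attrs])
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
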