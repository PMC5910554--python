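"""GFF3 export of protein-peptide alignments for genome-browser display.

Each protein becomes a ``polypeptide`` feature spanning its full length and
each peptide occurrence a ``peptide`` feature anchored at its residue
coordinates (1-based inclusive, the native GFF3 convention).  The source
column carries the enzyme id and a ``miscleavage=<level>`` attribute carries
the level, so a browser renders one track per enzyme with per-level
subtracks.  Matched peptides additionally carry ``bioactivity`` and
``sources`` attributes — the payload a browser shows as a popup tooltip.

Peptides on proteins have no meaningful strand or phase; "+" and "." are
emitted as inert constants to satisfy the column grammar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate import MatchRecord
from .digestion import PeptideFragment, ProteinRecord

__all__ = ["GffFeature", "features_for_protein", "write_gff", "write_track_hints"]

# GFF3 reserves ; = & , % and whitespace controls inside attribute values.
_ENCODE = {c: f"%{ord(c):02X}" for c in ";=&,\t\n\r"}


def _encode_value(value: str) -> str:
    value = str(value).replace("%", "%25")
    for ch, rep in _ENCODE.items():
        value = value.replace(ch, rep)
    return value


@dataclass(frozen=True)
class GffFeature:
    seqid: str
    source: str
    type: str  # "polypeptide" | "peptide"
    start: int  # 1-based inclusive
    end: int
    attributes: tuple  # ordered (key, value) pairs
    score: str = "."
    strand: str = "+"
    phase: str = "."

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature span {self.start}..{self.end}")

    def attribute(self, key, default=None):
        for k, v in self.attributes:
            if k == key:
                return v
        return default

    def line(self) -> str:
        attrs = ";".join(f"{k}={_encode_value(v)}" for k, v in self.attributes)
        return "\t".join(
            (
                self.seqid,
                self.source,
                self.type,
                str(self.start),
                str(self.end),
                self.score,
                self.strand,
                self.phase,
                attrs,
            )
        )


def features_for_protein(
    protein: ProteinRecord,
    fragments: Sequence[PeptideFragment],
    match_records: Sequence[MatchRecord] = (),
    which: str = "matched_only",
) -> list:
    """Features for one protein: the polypeptide plus peptide occurrences.

    ``which`` selects ``matched_only`` (bioactive peptides, the browser's
    discovery view) or ``all`` (every fragment, for digestion design).
    """
    if which not in ("matched_only", "all"):
        raise ValueError(f"which must be 'matched_only' or 'all', got {which!r}")
    L = len(protein)
    pid = protein.protein_id
    for frag in fragments:
        if frag.protein_id != pid:
            raise ValueError(f"fragment from foreign protein {frag.protein_id!r}")
        if frag.end > L:
            raise ValueError(f"fragment {frag.start}..{frag.end} beyond protein length {L}")

    # Annotation payload per matched (sequence, enzyme, level).
    annotation = {}
    for rec in match_records:
        annotation[rec.peptide.key] = (
            ";".join(rec.activities()),
            ";".join(rec.source_dbs()),
        )

    features = [
        GffFeature(
            seqid=pid,
            source="input",
            type="polypeptide",
            start=1,
            end=L,
            attributes=(("ID", pid), ("Name", pid)),
        )
    ]
    for n, frag in enumerate(
        sorted(fragments, key=lambda f: (f.enzyme_id, f.level, f.start, f.end)), start=1
    ):
        key = (frag.sequence, frag.enzyme_id, frag.level)
        matched = key in annotation
        if which == "matched_only" and not matched:
            continue
        attrs = [
            ("ID", f"{pid}.{frag.enzyme_id}.m{frag.level}.{n:05d}"),
            ("Name", frag.sequence),
            ("miscleavage", str(frag.level)),
        ]
        if matched:
            activities, sources = annotation[key]
            attrs.append(("bioactivity", activities))
            attrs.append(("sources", sources))
        features.append(
            GffFeature(
                seqid=pid,
                source=frag.enzyme_id,
                type="peptide",
                start=frag.start,
                end=frag.end,
                attributes=tuple(attrs),
            )
        )
    return features


def write_gff(features: Iterable[GffFeature], path) -> None:
    """Write sorted features with version directive and sequence-region lines."""
    features = sorted(features, key=lambda f: (f.seqid, f.start, f.end, f.source, f.type))
    ids = [f.attribute("ID") for f in features]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature IDs: {dup[:5]}")
    regions = {}
    for feat in features:
        if feat.type == "polypeptide":
            regions[feat.seqid] = feat.end
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for seqid in sorted(regions):
            fh.write(f"##sequence-region {seqid} 1 {regions[seqid]}\n")
        for feat in features:
            fh.write(feat.line() + "\n")


def write_track_hints(features: Iterable[GffFeature], path) -> None:
    """Plain-text sidecar mapping browser tracks to sources and subtracks."""
    tracks: dict = {}
    for feat in features:
        if feat.type != "peptide":
            continue
        level = feat.attribute("miscleavage", "0")
        tracks.setdefault(feat.source, set()).add(level)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# track\tsubtracks (miscleavage levels)\n")
        fh.write("input\tpolypeptide backbone\n")
        for source in sorted(tracks):
            levels = ",".join(sorted(tracks[source], key=int))
            fh.write(f"{source}\tmiscleavage={levels}\n")
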