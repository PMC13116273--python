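"""Reading, writing and normalizing annotated mitochondrial genomes.

Everything downstream (skew profiling, gene-order comparison, tRNA scoring,
codon usage) operates on :class:`AnnotatedMitogenome` records whose features
carry labels from one canonical vocabulary: 13 protein-coding genes, 2 rRNAs
and 22 tRNAs (leucine split into trnL1/CUN and trnL2/UUR, serine into
trnS1/AGN and trnS2/UCN).

Coordinates are 0-based half-open internally; GenBank and the feature-table
TSV convert at the boundary (both are 1-based inclusive on disk). A feature on
a circular genome may wrap the origin, in which case ``end <= start`` and
``wraps`` is set — wrapping genes are kept as a single feature so gene order
has exactly one entry per gene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# canonical vocabulary -------------------------------------------------------

PCGS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
)
RRNAS = ("rrnL", "rrnS")
TRNAS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)
CANONICAL = frozenset(PCGS) | frozenset(RRNAS) | frozenset(TRNAS)

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed input file or invalid genome record."""


class DegenerateCDSError(GenomeIOError):
    """A coding sequence too short to carry at least two codons."""


# domain types ---------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``start``/``end`` are 0-based half-open on the stored (major) strand;
    ``strand`` is +1/-1. For origin-wrapping features on circular genomes
    ``wraps`` is True and the span runs start..length then 0..end.
    """

    label: str
    cls: str  # PCG | tRNA | rRNA
    start: int
    end: int
    strand: int
    wraps: bool = False

    def span_length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A nucleotide sequence plus its ordered gene features."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> "AnnotatedMitogenome":
        """Check coordinate and topology invariants; return self."""
        n = self.length
        if n == 0:
            raise GenomeIOError(f"{self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"{self.id}: bad topology {self.topology!r}")
        for f in self.features:
            if not (0 <= f.start < n) or not (0 < f.end <= n):
                raise GenomeIOError(
                    f"{self.id}: feature {f.label} outside [0, {n}): "
                    f"({f.start}, {f.end})"
                )
            if f.wraps and self.topology != "circular":
                raise GenomeIOError(
                    f"{self.id}: wrapping feature {f.label} on linear genome"
                )
            if not f.wraps and f.end <= f.start:
                raise GenomeIOError(
                    f"{self.id}: feature {f.label} has end <= start "
                    "without wrap flag"
                )
            if f.strand not in (1, -1):
                raise GenomeIOError(f"{self.id}: bad strand on {f.label}")
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            self.features.sort(key=lambda f: (f.start, f.end))
        return self

    def feature_seq(self, f: GeneFeature) -> str:
        """Span sequence on the major strand (not strand-corrected)."""
        if f.wraps:
            return self.sequence[f.start:] + self.sequence[: f.end]
        return self.sequence[f.start : f.end]


# label normalization --------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "glu": "E",
    "gln": "Q", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_PCG_ALIASES: dict[str, str] = {}
for _i in range(1, 7):
    for _a in (f"nad{_i}", f"nd{_i}", f"nadh{_i}",
               f"nadh dehydrogenase subunit {_i}"):
        _PCG_ALIASES[_a] = f"ND{_i}"
for _a in ("nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l"):
    _PCG_ALIASES[_a] = "ND4L"
_ROMAN = {"1": "i", "2": "ii", "3": "iii"}
for _i in "123":
    for _a in (f"cox{_i}", f"co{_i}", f"cox {_i}", f"co{_ROMAN[_i]}",
               f"cox{_ROMAN[_i]}",
               f"cytochrome c oxidase subunit {_i}",
               f"cytochrome c oxidase subunit {_ROMAN[_i]}"):
        _PCG_ALIASES[_a] = f"COX{_i}"
for _a in ("cytb", "cob", "cytochrome b", "cytochrome b apoenzyme"):
    _PCG_ALIASES[_a] = "CYTB"
for _i in ("6", "8"):
    for _a in (f"atp{_i}", f"atpase{_i}", f"atpase {_i}",
               f"atp synthase f0 subunit {_i}",
               f"atp synthase subunit {_i}"):
        _PCG_ALIASES[_a] = f"ATP{_i}"

_RRNA_ALIASES = {
    "rrnl": "rrnL", "16s": "rrnL", "16s rrna": "rrnL",
    "16s ribosomal rna": "rrnL", "l-rrna": "rrnL", "lsu": "rrnL",
    "large subunit ribosomal rna": "rrnL", "rrn16": "rrnL", "mtlsu": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12s rrna": "rrnS",
    "12s ribosomal rna": "rrnS", "s-rrna": "rrnS", "ssu": "rrnS",
    "small subunit ribosomal rna": "rrnS", "rrn12": "rrnS", "mtssu": "rrnS",
}

# anticodon (DNA or RNA spelling, lowercase) -> leucine/serine isoacceptor
_LS_BY_ANTICODON = {
    "tag": "trnL1", "uag": "trnL1",   # CUN family
    "taa": "trnL2", "uaa": "trnL2",   # UUR family
    "gct": "trnS1", "gcu": "trnS1",   # AGN family
    "tga": "trnS2", "uga": "trnS2",   # UCN family
}
_LS_BY_FAMILY = {
    "cun": "trnL1", "uur": "trnL2", "ttr": "trnL2",
    "agn": "trnS1", "agy": "trnS1", "ucn": "trnS2", "tcn": "trnS2",
}


def _norm_trna(body: str, anticodon: str | None) -> str:
    """Resolve a tRNA name body like 'l1', 'leu', 'l(tag)' to a label."""
    paren = re.search(r"\(([a-z]{3})\)", body)
    hint = paren.group(1) if paren else None
    body = re.sub(r"\(.*?\)", "", body).strip(" -_")
    if body in ("l1", "l2", "s1", "s2"):
        return "trn" + body.upper()
    aa = None
    if len(body) == 1 and body.upper() in _AA3_TO_1.values():
        aa = body.upper()
    elif body[:3] in _AA3_TO_1:
        aa = _AA3_TO_1[body[:3]]
    if aa is None:
        return "unknown"
    if aa not in ("L", "S"):
        label = "trn" + aa
        return label if label in CANONICAL else "unknown"
    # leucine/serine need the anticodon or a family hint to disambiguate
    for key in (anticodon, hint):
        if key is None:
            continue
        key = key.lower()
        if key in _LS_BY_ANTICODON:
            return _LS_BY_ANTICODON[key]
        if key in _LS_BY_FAMILY:
            return _LS_BY_FAMILY[key]
    return f"trn{aa}?"  # carried but excluded from presence scoring


def normalize_label(raw: str, cls: str | None = None,
                    anticodon: str | None = None) -> tuple[str, str]:
    """Map a gene/product name from any common dialect onto the canonical
    vocabulary.

    Returns ``(label, cls)``; unmappable strings yield ``("unknown", cls)``
    with the class as annotated (PCG when no hint is available). Never raises.
    """
    if not raw or not raw.strip():
        return "unknown", cls or PCG
    s = raw.strip()
    low = s.lower().replace("_", " ").strip()
    if s in CANONICAL:  # canonical labels are fixed points
        if s in PCGS:
            return s, PCG
        return (s, RRNA) if s in RRNAS else (s, TRNA)
    key = low.replace("-", " ").strip()
    if key in _PCG_ALIASES:
        return _PCG_ALIASES[key], PCG
    if key in _RRNA_ALIASES:
        return _RRNA_ALIASES[key], RRNA
    if low.startswith("trna") or low.startswith("trn"):
        body = low[4:] if low.startswith("trna") else low[3:]
        body = body.strip(" -_")
        if not body and low == "trna":  # bare lowercase "trna" = tRNA-Ala
            body = "a"
        label = _norm_trna(body, anticodon)
        if label != "unknown":
            return label, TRNA
        return "unknown", cls or TRNA
    return "unknown", cls or PCG


# GenBank / FASTA / TSV ------------------------------------------------------

_FEATURE_TYPES = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA}
_CLS_TO_TYPE = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA"}


def _location_to_coords(loc, length: int) -> tuple[int, int, int, bool]:
    """Collapse a (possibly origin-spanning compound) location."""
    strand = 1 if (loc.strand is None or loc.strand >= 0) else -1
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end), strand, False
    if (len(parts) == 2 and int(parts[0].start) == 0
            and int(parts[1].end) == length):
        # join(x..length, 1..y): single gene wrapping the origin
        return int(parts[1].start), int(parts[0].end), strand, True
    raise GenomeIOError(f"unsupported compound location {loc}")


def read_genbank(path) -> list[AnnotatedMitogenome]:
    """Read a (multi-record) GenBank flat file into genome records.

    Coordinates convert from GenBank 1-based inclusive to 0-based half-open
    (Biopython already does this); ``join`` spans across the origin collapse
    into one wrapping feature; topology comes from the LOCUS line.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        topology = rec.annotations.get("topology", "linear")
        feats: list[GeneFeature] = []
        for f in rec.features:
            if f.type not in _FEATURE_TYPES:
                continue
            cls = _FEATURE_TYPES[f.type]
            raw = (f.qualifiers.get("gene") or f.qualifiers.get("product")
                   or ["unknown"])[0]
            anti = None
            if "anticodon" in f.qualifiers:
                m = re.search(r"seq[:=]\s*([a-zA-Z]{3})",
                              f.qualifiers["anticodon"][0])
                anti = (m.group(1) if m
                        else f.qualifiers["anticodon"][0].strip("() "))
            label, cls = normalize_label(raw, cls, anticodon=anti)
            if label == "unknown":
                logger.warning("%s: unknown gene label %r kept as-is",
                               rec.id, raw)
            start, end, strand, wraps = _location_to_coords(
                f.location, len(seq))
            feats.append(GeneFeature(label, cls, start, end, strand, wraps))
        g = AnnotatedMitogenome(rec.id, seq, topology, feats)
        genomes.append(g.validate())
    if not genomes:
        raise GenomeIOError(f"{path}: no GenBank records found")
    return genomes


def write_genbank(genomes, path) -> None:
    """Write genomes as a multi-record GenBank flat file (lossless for the
    fields this package models)."""
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16],
                        description=f"{g.id} mitochondrial genome")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        rec.annotations["date"] = "01-JAN-2000"  # fixed for determinism
        rec.annotations["data_file_division"] = "INV"
        for f in g.features:
            if f.wraps:
                loc = CompoundLocation([
                    FeatureLocation(f.start, g.length, strand=f.strand),
                    FeatureLocation(0, f.end, strand=f.strand),
                ])
            else:
                loc = FeatureLocation(f.start, f.end, strand=f.strand)
            quals = {"gene": [f.label]}
            records_type = _CLS_TO_TYPE[f.cls]
            rec.features.append(SeqFeature(loc, type=records_type,
                                           qualifiers=quals))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_fasta(path) -> list[AnnotatedMitogenome]:
    """Read bare sequences (no features) from FASTA."""
    out = [AnnotatedMitogenome(rec.id, str(rec.seq).upper(), "circular", [])
           for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return out


def write_fasta(genomes, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes],
        str(path), "fasta")


def read_feature_table(path) -> dict[str, list[GeneFeature]]:
    """Feature-table TSV (columns id, label, cls, start, end, strand; 1-based
    inclusive; end < start denotes an origin-wrapping feature)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "label", "cls", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise GenomeIOError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    tables: dict[str, list[GeneFeature]] = {}
    for row in df.itertuples(index=False):
        start1, end1 = int(row.start), int(row.end)
        wraps = end1 < start1
        feat = GeneFeature(str(row.label), str(row.cls), start1 - 1, end1,
                           int(row.strand), wraps)
        tables.setdefault(str(row.id), []).append(feat)
    return tables


def write_feature_table(genomes, path) -> None:
    rows = [
        {"id": g.id, "label": f.label, "cls": f.cls, "start": f.start + 1,
         "end": f.end, "strand": f.strand}
        for g in genomes for f in g.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# CDS extraction and anchoring ----------------------------------------------


def extract_cds(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Strand-corrected coding sequence, trimmed to a codon multiple.

    Mitochondrial genes often end on incomplete stop codons completed by
    polyadenylation; the trailing 1-2 bases are trimmed so the result is a
    multiple of 3.
    """
    if feature.cls != PCG:
        raise GenomeIOError(f"{feature.label} is not a PCG feature")
    s = genome.feature_seq(feature)
    if feature.strand == -1:
        s = revcomp(s)
    if len(s) % 3:
        s = s[: len(s) - len(s) % 3]
    if len(s) < 6:
        raise DegenerateCDSError(
            f"{genome.id}:{feature.label} CDS shorter than 2 codons")
    return s


def _shift_feature(f: GeneFeature, offset: int, length: int) -> GeneFeature:
    start = (f.start - offset) % length
    end0 = (f.end - offset) % length
    end = end0 if end0 != 0 else length
    return replace(f, start=start, end=end, wraps=end <= start)


def _revcomp_feature(f: GeneFeature, length: int) -> GeneFeature:
    if f.wraps:
        start, end0 = (length - f.end) % length, (length - f.start) % length
    else:
        start, end0 = length - f.end, length - f.start
    end = end0 if end0 != 0 else length
    return replace(f, start=start, end=end, strand=-f.strand,
                   wraps=end <= start)


def anchor_genome(genome: AnnotatedMitogenome,
                  label: str = "COX1") -> AnnotatedMitogenome:
    """Rotate (and if needed reflect) a circular genome so that the anchor
    gene starts at position 0 on the plus strand.

    Cross-species skew landscapes are only comparable on a common
    orientation, so profiles are computed on this anchoring. Linear genomes
    are returned unchanged.
    """
    if genome.topology != "circular":
        return genome
    hits = [f for f in genome.features if f.label == label]
    if not hits:
        raise GenomeIOError(f"{genome.id}: anchor gene {label} absent")
    anchor = hits[0]
    seq, feats, n = genome.sequence, genome.features, genome.length
    if anchor.strand == -1:
        seq = revcomp(seq)
        feats = [_revcomp_feature(f, n) for f in feats]
        anchor = _revcomp_feature(anchor, n)
    offset = anchor.start
    seq = seq[offset:] + seq[:offset]
    feats = sorted((_shift_feature(f, offset, n) for f in feats),
                   key=lambda f: (f.start, f.end))
    return AnnotatedMitogenome(genome.id, seq, "circular", feats).validate()
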