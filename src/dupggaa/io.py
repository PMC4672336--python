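"""Sequence and annotation I/O, TSS-relative promoter windows, and match export.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  TSS-relative labels — the
``-500 .. +100`` style positions used in promoter literature — are
presentation-only: 1-based and zero-skipping, so position ``-1`` abuts ``+1``
and there is no position 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .scan import MotifMatch

logger = logging.getLogger("dupggaa")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
#: IUPAC one-letter nucleotide codes other than A/C/G/T/N; mapped to N on input.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVU")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, seq_id: str = "?") -> str:
    """Uppercase ``seq`` and map ambiguous IUPAC codes to N.

    Raises ``ValueError`` for characters that are not nucleotide codes at all.
    Substitutions are counted and logged so silent data loss is visible.
    """
    up = seq.upper()
    n_subst = 0
    out = []
    for ch in up:
        if ch in "ACGTN":
            out.append(ch)
        elif ch in _IUPAC_AMBIGUOUS:
            out.append("N")
            n_subst += 1
        else:
            raise ValueError(f"invalid character {ch!r} in sequence {seq_id!r}")
    if n_subst:
        logger.warning(
            "sequence %s: %d ambiguous IUPAC character(s) replaced with N",
            seq_id, n_subst,
        )
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N} (stored uppercase)."""

    id: str
    seq: str
    set_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=revcomp(self.seq))


@dataclass(frozen=True)
class TssAnnotation:
    """A transcription start site on a contig; ``tss_coordinate`` is 1-based (+1 base)."""

    contig_id: str
    tss_coordinate: int
    strand: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss_coordinate < 1:
            raise ValueError("tss_coordinate must be >= 1 (1-based)")


@dataclass(frozen=True)
class PromoterWindow:
    """A TSS-anchored promoter window.

    The window sequence reads 5'→3' with the upstream segment first; the +1
    base is the first base of the downstream segment, i.e. at 0-based index
    ``upstream_extent`` within ``record.seq``.
    """

    record: SequenceRecord
    upstream_extent: int = 500
    downstream_extent: int = 100

    def __post_init__(self) -> None:
        if self.upstream_extent <= 0 or self.downstream_extent <= 0:
            raise ValueError("window extents must be positive")
        expected = self.upstream_extent + self.downstream_extent
        if len(self.record.seq) != expected:
            raise ValueError(
                f"window {self.record.id!r}: sequence length {len(self.record.seq)} "
                f"!= upstream + downstream = {expected}"
            )

    @property
    def tss_offset(self) -> int:
        """0-based index of the +1 base within the window sequence."""
        return self.upstream_extent

    def tss_label(self, index: int) -> int:
        """TSS-relative, zero-skipping label of 0-based window ``index``."""
        if not 0 <= index < len(self.record.seq):
            raise IndexError(f"index {index} outside window of length {len(self.record.seq)}")
        off = index - self.tss_offset
        return off + 1 if off >= 0 else off


def tss_label_add(label: int, offset: int) -> int:
    """Advance a zero-skipping TSS-relative label by ``offset`` bases.

    Used to place motif coordinates on probes whose first base carries a known
    promoter label (e.g. a probe starting at -340).
    """
    if label == 0:
        raise ValueError("TSS-relative labels skip zero")
    raw = label + offset
    if label < 0 and raw >= 0:
        raw += 1
    elif label > 0 and raw <= 0:
        raw -= 1
    return raw


def format_label(label: int) -> str:
    return f"+{label}" if label > 0 else str(label)


# ---------------------------------------------------------------------------
# FASTA / TSV
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path], set_label: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Sequences are uppercased, ambiguous IUPAC codes become N (logged), and
    duplicate ids raise an error naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(entry.id, normalize_sequence(str(entry.seq), entry.id), set_label)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: Union[str, Path],
    description: str = "",
) -> None:
    """Write records as FASTA; ``description`` (e.g. model/seed provenance) is
    appended to every header line."""
    out = [
        SeqRecord(Seq(r.seq), id=r.id, description=description)
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def read_tss_table(path: Union[str, Path]) -> list[TssAnnotation]:
    """Read a TSS annotation TSV with columns: contig_id, tss_coordinate, strand, gene_id."""
    path = Path(path)
    rows: list[TssAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            contig, tss, strand = parts[0], parts[1], parts[2]
            gene = parts[3] if len(parts) > 3 else ""
            rows.append(TssAnnotation(contig, int(tss), strand, gene))
    if not rows:
        raise ValueError(f"no TSS rows found in {path}")
    return rows


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_window(
    contig: SequenceRecord,
    tss: TssAnnotation,
    upstream_extent: int = 500,
    downstream_extent: int = 100,
) -> PromoterWindow:
    """Extract the TSS-relative promoter window from a contig.

    For a '+' strand TSS at 1-based coordinate ``t`` the window covers contig
    bases ``t - upstream`` .. ``t + downstream - 1`` (1-based, inclusive).  For
    a '-' strand TSS the mirror-image interval is taken and
    reverse-complemented so the returned window always reads upstream-first.
    Windows that overrun a contig edge raise (no silent clipping).
    """
    t = tss.tss_coordinate
    L = len(contig.seq)
    if t > L:
        raise ValueError(f"TSS coordinate {t} beyond contig {contig.id!r} length {L}")
    if tss.strand == "+":
        start1, end1 = t - upstream_extent, t + downstream_extent - 1
    else:
        start1, end1 = t - downstream_extent + 1, t + upstream_extent
    if start1 < 1 or end1 > L:
        raise ValueError(
            f"window out of bounds for TSS {tss.gene_id or tss.contig_id}@{t}"
            f"({tss.strand}): contig positions {start1}..{end1} vs length {L}"
        )
    seq = contig.seq[start1 - 1 : end1]
    if tss.strand == "-":
        seq = revcomp(seq)
    win_id = tss.gene_id or f"{tss.contig_id}:{t}{tss.strand}"
    high_n = seq.count("N") / len(seq) > 0.5
    if high_n:
        logger.warning("window %s: more than 50%% N content", win_id)
    return PromoterWindow(
        SequenceRecord(win_id, seq, contig.set_label),
        upstream_extent,
        downstream_extent,
    )


# ---------------------------------------------------------------------------
# BED export + text feature map
# ---------------------------------------------------------------------------

def _match_name(match: "MotifMatch", core: str = "GGAA") -> str:
    words = {"F": core, "R": revcomp(core)}
    return f"{words[match.pair_type[0]]}-{words[match.pair_type[1]]}/s{match.spacer}"


def write_bed(
    matches: Iterable["MotifMatch"],
    windows: Union[PromoterWindow, SequenceRecord, Iterable[Union[PromoterWindow, SequenceRecord]]],
    path: Union[str, Path],
    feature_map_path: Union[str, Path, None] = None,
    core: str = "GGAA",
) -> None:
    """Write matches as BED6 plus a sidecar text feature map.

    BED coordinates are 0-based half-open relative to each window/record.  The
    name field encodes the core pair and spacer (``TTCC-TTCC/s2``); the strand
    column is '+' for matches anchored on the sense strand and '-' for matches
    only representable on the antisense strand.  The feature map lists
    TSS-relative labels where the target is a :class:`PromoterWindow`, raw
    0-based coordinates otherwise.
    """
    if isinstance(windows, (PromoterWindow, SequenceRecord)):
        windows = [windows]
    by_id: dict[str, Union[PromoterWindow, SequenceRecord]] = {}
    for w in windows:
        rid = w.record.id if isinstance(w, PromoterWindow) else w.id
        by_id[rid] = w

    path = Path(path)
    fmap_path = Path(feature_map_path) if feature_map_path else path.with_suffix(path.suffix + ".fmap.txt")
    bed_lines: list[str] = []
    fmap_lines: list[str] = []
    for m in matches:
        if m.seq_id not in by_id:
            raise ValueError(f"match references unknown sequence {m.seq_id!r}")
        target = by_id[m.seq_id]
        seq_len = len(target.record.seq) if isinstance(target, PromoterWindow) else len(target.seq)
        if not (0 <= m.start < m.end <= seq_len):
            raise ValueError(
                f"match {m.start}..{m.end} outside sequence {m.seq_id!r} of length {seq_len}"
            )
        strand = "+" if "+" in m.strand_set else "-"
        name = _match_name(m, core)
        bed_lines.append(f"{m.seq_id}\t{m.start}\t{m.end}\t{name}\t0\t{strand}")
        if isinstance(target, PromoterWindow):
            span = f"{format_label(target.tss_label(m.start))}..{format_label(target.tss_label(m.end - 1))}"
        else:
            span = f"{m.start}..{m.end - 1}"
        fmap_lines.append(f"{m.seq_id}\t{span}\t{name}\t{strand}")
    path.write_text("".join(line + "\n" for line in bed_lines))
    fmap_path.write_text("".join(line + "\n" for line in fmap_lines))


# ---------------------------------------------------------------------------
# Bundled fixture: EMSA duplex probes
# ---------------------------------------------------------------------------

#: TSS-relative label of the first base of each anchored probe (None: synthetic).
PROBE_START_LABELS: dict[str, int | None] = {
    "OAS1_-340_-301": -340,
    "OAS1_-379_-331": -379,
    "OAS1_-330_-301": -330,
    "mtTTCC1": -330,
    "mtTTCC2": -330,
    "dupGGAA_competitor": None,
}


def load_emsa_probes() -> list[SequenceRecord]:
    """The six double-stranded EMSA duplex probes bundled with the package.

    Four derive from the human OAS1 promoter (the -340/-301 region containing
    the duplicated GGAA motif, its two core-mutant variants, and an adjacent
    non-specific region); the sixth is a synthetic duplicated-GGAA competitor.
    Sense strands only.
    """
    ref = resources.files("dupggaa").joinpath("data/emsa_probes.fasta")
    with resources.as_file(ref) as p:
        return read_fasta(p, set_label="emsa_probe")
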