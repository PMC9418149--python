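"""Sequence input and reference-frame anchoring.

Reads control-region FASTA plus a sample->population/region map, anchors
each sequence to the reference coordinate frame by global pairwise
alignment, and scores substitutions as ``<anc><pos><der>`` tokens.

Insertions relative to the reference are recorded on the
:class:`AlignedSequence` but excluded from the fixed coordinate frame
and from every downstream statistic; IUPAC ambiguity codes are treated
as missing so they can never produce a spurious motif match.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .reference import ReferenceFrame

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

# Fixed alignment parameters, chosen once for bit-reproducible outputs.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN_SCORE = -4.0
GAP_EXTEND_SCORE = -1.0
MIN_IDENTITY = 0.70
LENGTH_TOLERANCE = 0.20

_TOKEN_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True)
class SequenceRecord:
    """One raw input sequence with its sampling metadata."""

    sample_id: str
    raw_seq: str
    population: str
    region: str = ""


@dataclass(frozen=True)
class Substitution:
    """A single substitution relative to the reference frame."""

    position: int  # 1-based
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError(f"substitution at {self.position}: states identical")

    @property
    def token(self) -> str:
        return f"{self.ancestral}{self.position}{self.derived}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def parse_token(token: str) -> Substitution:
    """Parse a motif token such as ``A281G``."""
    m = _TOKEN_RE.match(token.strip().upper())
    if not m:
        raise ValueError(f"malformed substitution token: {token!r}")
    return Substitution(position=int(m.group(2)), ancestral=m.group(1), derived=m.group(3))


@dataclass(frozen=True)
class VariantSet:
    """Ordered substitutions of one sample (at most one per position)."""

    sample_id: str
    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.sample_id}: multiple substitutions at one position")
        object.__setattr__(
            self,
            "substitutions",
            tuple(sorted(self.substitutions, key=lambda s: s.position)),
        )

    @property
    def tokens(self) -> frozenset[str]:
        return frozenset(s.token for s in self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)


@dataclass
class AlignedSequence:
    """Per-position base calls of one sample in reference coordinates.

    ``states[i]`` is the call at reference position ``i + 1``: one of
    A/C/G/T, ``-`` (gap: deleted or unaligned) or ``N`` (missing /
    ambiguous). ``insertions`` maps the reference position *after* which
    inserted bases occur to the inserted string.
    """

    sample_id: str
    states: str
    insertions: dict[int, str] = field(default_factory=dict)

    @property
    def n_gaps(self) -> int:
        return self.states.count("-")

    @property
    def n_missing(self) -> int:
        return self.states.count("N")


def read_fasta(fasta_path: str | Path, popmap_path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA plus its popmap TSV into :class:`SequenceRecord` list.

    The popmap must have columns ``sample_id``, ``population``,
    ``region``. Every FASTA id must appear in the popmap; extra popmap
    rows are ignored with a warning. Duplicate ids are an error.
    """
    fasta_path = Path(fasta_path)
    popmap = pd.read_csv(popmap_path, sep="\t", dtype=str)
    required = {"sample_id", "population", "region"}
    if not required <= set(popmap.columns):
        raise ValueError(f"popmap must have columns {sorted(required)}")
    if popmap["sample_id"].duplicated().any():
        dups = popmap.loc[popmap["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in popmap: {dups}")
    meta = popmap.set_index("sample_id")

    handle = gzip.open(fasta_path, "rt") if fasta_path.suffix == ".gz" else open(fasta_path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id in FASTA: {rec.id}")
            seen.add(rec.id)
            if rec.id not in meta.index:
                raise ValueError(f"sample {rec.id!r} missing from popmap")
            row = meta.loc[rec.id]
            records.append(
                SequenceRecord(
                    sample_id=rec.id,
                    raw_seq=str(rec.seq).upper(),
                    population=str(row["population"]),
                    region=str(row["region"]) if pd.notna(row["region"]) else "",
                )
            )
    extras = set(meta.index) - seen
    if extras:
        logger.warning("popmap has %d entries absent from FASTA (ignored)", len(extras))
    return records


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


_ALIGNER = _make_aligner()


def anchor_to_reference(record: SequenceRecord, ref: ReferenceFrame) -> AlignedSequence:
    """Globally align a raw sequence to the reference frame.

    Raises if the sequence length falls outside ±20% of the frame or if
    alignment identity over called positions is below 70% ("does not
    resemble the chicken control region").
    """
    L = ref.length
    seq = record.raw_seq.upper().replace("U", "T")
    if not (1 - LENGTH_TOLERANCE) * L <= len(seq) <= (1 + LENGTH_TOLERANCE) * L:
        raise ValueError(
            f"{record.sample_id}: length {len(seq)} outside "
            f"[{(1 - LENGTH_TOLERANCE) * L:.0f}, {(1 + LENGTH_TOLERANCE) * L:.0f}]"
        )
    # Ambiguity codes are aligned as-is, then masked to missing.
    alignment = _ALIGNER.align(ref.sequence, seq)[0]
    target_blocks, query_blocks = alignment.aligned

    states = ["-"] * L
    insertions: dict[int, str] = {}
    prev_t = prev_q = 0
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        if q0 > prev_q and t0 == prev_t:
            # query bases consumed without advancing the reference
            insertions[t0] = seq[prev_q:q0]
        states[t0:t1] = list(seq[q0:q1])
        prev_t, prev_q = t1, q1

    called = sum(1 for s in states if s in _BASES)
    matches = sum(1 for i, s in enumerate(states) if s in _BASES and s == ref.sequence[i])
    if called == 0 or matches / called < MIN_IDENTITY:
        raise ValueError(
            f"{record.sample_id}: sequence does not resemble the chicken control region "
            f"(identity {matches / max(called, 1):.2f} < {MIN_IDENTITY})"
        )
    # Mask IUPAC ambiguity codes (anything not ACGT or gap) as missing.
    states = [s if s in _BASES or s == "-" else "N" for s in states]
    return AlignedSequence(sample_id=record.sample_id, states="".join(states), insertions=insertions)


def call_substitutions(aln: AlignedSequence, ref: ReferenceFrame) -> VariantSet:
    """Score substitutions of an anchored sequence against the reference.

    Gap and missing positions produce no call; an empty set is valid.
    """
    if len(aln.states) != ref.length:
        raise ValueError("aligned sequence not in the reference frame")
    subs = [
        Substitution(position=i + 1, ancestral=ref.sequence[i], derived=s)
        for i, s in enumerate(aln.states)
        if s in _BASES and s != ref.sequence[i]
    ]
    return VariantSet(sample_id=aln.sample_id, substitutions=tuple(subs))


def apply_variants(ref: ReferenceFrame, vs: VariantSet) -> str:
    """Reference sequence with a variant set applied (round-trip helper)."""
    seq = list(ref.sequence)
    for s in vs.substitutions:
        if ref.sequence[s.position - 1] != s.ancestral:
            raise ValueError(f"{s.token}: ancestral state disagrees with reference")
        seq[s.position - 1] = s.derived
    return "".join(seq)


def write_variants_tsv(variant_sets: list[VariantSet], path: str | Path) -> None:
    """Variants TSV: sample_id, comma-joined motif tokens."""
    with open(path, "w") as fh:
        fh.write("sample_id\tsubstitutions\n")
        for vs in variant_sets:
            fh.write(f"{vs.sample_id}\t{','.join(s.token for s in vs.substitutions)}\n")
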