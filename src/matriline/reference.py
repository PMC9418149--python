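"""Reference coordinate frame for the chicken mtDNA control region.

All downstream coordinates are 1-based inclusive positions on a single
reference sequence (the 1232-bp complete D-loop frame of the chicken
mitogenome reference NC_040970). Substitutions are rendered as tokens
``<anc><pos><der>`` (e.g. ``A281G``) relative to this frame.

The package bundles a *synthetic* stand-in reference
(``data/synthetic_reference.fasta``): a deterministic pseudo-random
1232-bp sequence whose bases at every diagnostic haplogroup-motif
position equal the ancestral state of the corresponding published motif
token, so the bundled motif scheme is loadable and classifiable without
access to sequence databases. Users analysing real data should supply
the true reference via ``load_reference``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

CONTROL_REGION_LENGTH = 1232

_BASES = "ACGT"

# Ancestral-state constraints at diagnostic motif positions (1-based).
# The first ten come from the published V / V2 / D1b token sets; the rest
# anchor the synthetic placeholder motifs of the bundled scheme.
_ANCHORED_BASES = {
    228: "C", 237: "A", 281: "A", 296: "C", 306: "T",
    342: "A", 355: "T", 363: "C", 391: "C", 686: "G",
    167: "C", 415: "A", 447: "C", 510: "A", 563: "G",
    727: "T", 775: "C", 893: "T", 912: "A", 988: "A",
}

_SYNTHETIC_SEED = 40970
_SYNTHETIC_ID = "SYNTH_DLOOP_1232"


@dataclass(frozen=True)
class ReferenceFrame:
    """A reference sequence defining the 1-based coordinate frame.

    ``reference_id`` defaults to the chicken mitogenome accession the
    field scores control-region motifs against; arbitrary lengths are
    allowed so that small toy frames can be used in validation.
    """

    reference_id: str = "NC_040970"
    sequence: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - set(_BASES)
        if bad:
            raise ValueError(f"reference contains non-ACGT symbols: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]


def synthetic_reference() -> ReferenceFrame:
    """Deterministically regenerate the bundled synthetic reference.

    Pseudo-random ACGT sequence of length 1232 from a fixed seed, with
    diagnostic motif positions pinned to their ancestral states. The
    bundled FASTA fixture is the serialization of this sequence.
    """
    rng = np.random.default_rng(_SYNTHETIC_SEED)
    seq = list("".join(rng.choice(list(_BASES), size=CONTROL_REGION_LENGTH)))
    for pos, base in _ANCHORED_BASES.items():
        seq[pos - 1] = base
    return ReferenceFrame(reference_id=_SYNTHETIC_ID, sequence="".join(seq))


def load_reference(path: str | Path) -> ReferenceFrame:
    """Load the first record of a (optionally gzipped) FASTA as the frame."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = None
        chunks: list[str] = []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    break
                header = line[1:].split()[0]
            elif header is not None:
                chunks.append(line)
    if header is None:
        raise ValueError(f"{path}: no FASTA record found")
    return ReferenceFrame(reference_id=header, sequence="".join(chunks))


def default_reference() -> ReferenceFrame:
    """The packaged synthetic control-region reference frame."""
    with resources.as_file(
        resources.files("matriline.data") / "synthetic_reference.fasta"
    ) as p:
        return load_reference(p)


def write_reference_fixture(path: str | Path) -> None:
    """Serialize the synthetic reference to FASTA (fixture maintenance)."""
    ref = synthetic_reference()
    with open(path, "w") as fh:
        fh.write(f">{ref.reference_id} synthetic stand-in control-region reference\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i : i + 70] + "\n")
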