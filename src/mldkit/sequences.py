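"""DNA sequence container, normalization and FASTA input.

Multi-record FASTA files are concatenated into a single working sequence
with an ``N`` joint between records (the same construction used to build a
"pseudogenome" from many short records); ``N`` never matches anything, so
no spurious match can span a record boundary.  Record identities and
offsets are retained so that match coordinates can be mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _normalization_table(mask_lowercase: bool) -> dict[int, str]:
    table = {}
    for code in range(256):
        ch = chr(code)
        up = ch.upper()
        if up in "ACGT":
            table[code] = "N" if (mask_lowercase and ch.islower()) else up
        else:
            table[code] = "N"
    return {k: v for k, v in table.items()}


_TABLE_PLAIN = str.maketrans({k: v for k, v in _normalization_table(False).items()})
_TABLE_MASKED = str.maketrans({k: v for k, v in _normalization_table(True).items()})


@dataclass
class Sequence:
    """A named DNA string over {A, C, G, T, N}.

    ``record_ids``/``record_offsets`` are populated when the sequence was
    assembled from a multi-record FASTA file; they map concatenated
    coordinates back to per-record coordinates.
    """

    id: str
    bases: str
    record_ids: list[str] | None = None
    record_offsets: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.bases)

    def locate(self, pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate to (record id, local position)."""
        if self.record_offsets is None or self.record_ids is None:
            return self.id, pos
        k = int(np.searchsorted(self.record_offsets, pos, side="right")) - 1
        return self.record_ids[k], pos - int(self.record_offsets[k])


def normalize_sequence(raw: str, mask_lowercase: bool = False, id: str = "") -> Sequence:
    """Uppercase and map every symbol outside {A,C,G,T} to N.

    With ``mask_lowercase`` set, lowercase (soft-masked) input additionally
    becomes N, emulating hard repeat masking.
    """
    table = _TABLE_MASKED if mask_lowercase else _TABLE_PLAIN
    return Sequence(id=id, bases=raw.translate(table))


def reverse_complement(seq: Sequence) -> Sequence:
    return Sequence(id=seq.id, bases=seq.bases.translate(_COMPLEMENT)[::-1])


def read_fasta(path, mask_lowercase: bool = False) -> Sequence:
    """Read a FASTA file into one (possibly concatenated) Sequence.

    Records are joined with a single ``N`` so that matches cannot span a
    record boundary.
    """
    ids: list[str] = []
    parts: list[str] = []
    offsets: list[int] = []
    pos = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if parts:
            pos += 1  # the N joint
        ids.append(rec.id)
        offsets.append(pos)
        norm = normalize_sequence(str(rec.seq), mask_lowercase=mask_lowercase)
        parts.append(norm.bases)
        pos += len(norm.bases)
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    seq_id = ids[0] if len(ids) == 1 else f"{ids[0]}+{len(ids) - 1}more"
    return Sequence(
        id=seq_id,
        bases="N".join(parts),
        record_ids=ids,
        record_offsets=np.asarray(offsets, dtype=np.int64),
    )
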