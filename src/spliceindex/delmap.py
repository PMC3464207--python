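"""Map a single genomic deletion between a wild-type and a mutant sequence.

The mutant is modelled as the wild type with one contiguous interval removed.
The breakpoint is located from the longest common prefix and suffix of the
two sequences; when flanking repeats allow the deletion to be placed at
several positions, the leftmost placement is reported (the VCF left-alignment
convention) together with the number of equivalent placements.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DeletionCall", "map_single_deletion"]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class DeletionCall:
    """Deletion on the WT sequence, 0-based half-open, leftmost placement."""

    start: int
    end: int
    ambiguity_span: int  # number of equivalent placements (1 = unique)

    @property
    def length(self) -> int:
        return self.end - self.start


def _bases_match(a: str, b: str) -> bool:
    # N is uninformative: it matches nothing, not even another N
    return a == b and a != "N"


def map_single_deletion(wt: str, mutant: str) -> DeletionCall:
    """Locate the unique-interval deletion turning ``wt`` into ``mutant``.

    Raises ``ValueError`` (naming the first mismatch position) when the
    mutant cannot be reconstructed by removing a single interval from the
    wild type — the signature of more than one variant.
    """
    wt = wt.upper()
    mutant = mutant.upper()
    if set(wt) - _ALPHABET or set(mutant) - _ALPHABET:
        raise ValueError("sequences must be over the A/C/G/T/N alphabet")
    if len(mutant) > len(wt):
        raise ValueError("mutant is longer than wild type; not a deletion")
    d = len(wt) - len(mutant)

    p = 0
    while p < len(mutant) and _bases_match(wt[p], mutant[p]):
        p += 1
    s = 0
    while s < len(mutant) - 0 and s < len(wt) and _bases_match(wt[len(wt) - 1 - s], mutant[len(mutant) - 1 - s]):
        s += 1
    s = min(s, len(mutant))

    left = max(0, len(mutant) - s)
    right = min(p, len(mutant))
    if left > right:
        raise ValueError(
            f"mutant is not a single deletion of wild type; first mismatch at position {p}"
        )
    start = left
    call = DeletionCall(start=start, end=start + d, ambiguity_span=right - left + 1)
    if wt[: call.start] + wt[call.end :] != mutant:
        raise ValueError("reconstruction check failed; sequences differ by more than one deletion")
    return call
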