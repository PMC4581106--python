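"""PCR primer design against a transcript, under hard constraint ranges.

A primer pair is searched around a target interval: the forward primer lies
entirely upstream of the target, the reverse primer is the reverse
complement of a window entirely downstream, and the product (forward start
to reverse end, inclusive) must fall within the configured amplicon range
while covering the target.  Each primer must satisfy length, GC-content and
melting-temperature ranges.

Melting temperature uses the GC-fraction formula

    Tm = 64.9 + 41 * (nGC - 16.4) / length

which is deterministic and parameter-free; the constraint window (not the
Tm model) is what the marker protocols prescribe.

The search is deterministic.  Candidate amplicon placements are ranked
either product-size-first (smallest product, then most-centered target,
then leftmost start) or centered-first (most-centered target, then smallest
product, then leftmost); within a placement the shortest feasible primer
length is chosen on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .iupac import reverse_complement
from .model import PrimerPair, SsrPrimerParams


def melting_temperature(primer: str) -> float:
    """GC-fraction melting temperature; requires length >= 14."""
    if len(primer) < 14:
        raise ValueError(f"primer shorter than 14 nt ({len(primer)})")
    gc = sum(1 for c in primer.upper() if c in "GC")
    return 64.9 + 41 * (gc - 16.4) / len(primer)


def gc_percent(primer: str) -> float:
    return 100 * sum(1 for c in primer.upper() if c in "GC") / len(primer)


@dataclass
class PrimerRejection:
    reason: str = "NO_PRIMER"
    constraint: str = ""  # the constraint that blocked most candidates


def _primer_window_ok(length: int, gc: int, params: SsrPrimerParams) -> tuple[bool, str]:
    pct = 100 * gc / length
    if not params.min_gc <= pct <= params.max_gc:
        return False, "GC"
    tm = 64.9 + 41 * (gc - 16.4) / length
    if not params.min_tm <= tm <= params.max_tm:
        return False, "TM"
    return True, ""


class _SideTable:
    """Memoized smallest feasible primer length per anchor position.

    For the forward side the anchor is the 0-based primer start; for the
    reverse side it is the 0-based *end* of the reverse-primer window.
    """

    def __init__(self, gc_prefix, params: SsrPrimerParams, forward: bool):
        self._gc = gc_prefix
        self._params = params
        self._forward = forward
        self._cache: dict[int, tuple[Optional[int], str]] = {}
        self._n = len(gc_prefix) - 1

    def min_len(self, anchor: int, max_space: int) -> tuple[Optional[int], str]:
        """Smallest feasible length <= max_space at this anchor, or (None, why)."""
        key = anchor
        if key not in self._cache:
            self._cache[key] = self._scan(anchor)
        length, why = self._cache[key]
        if length is not None and length > max_space:
            return None, "SPACE"
        return length, why

    def _scan(self, anchor: int) -> tuple[Optional[int], str]:
        p = self._params
        last_why = "SPACE"
        for length in range(p.min_length, p.max_length + 1):
            if self._forward:
                lo, hi = anchor, anchor + length
            else:
                lo, hi = anchor - length + 1, anchor + 1
            if lo < 0 or hi > self._n:
                continue
            ok, why = _primer_window_ok(length, self._gc[hi] - self._gc[lo], p)
            if ok:
                return length, ""
            last_why = why
        return None, last_why


def _placements(
    target_start: int,
    target_end: int,
    seq_len: int,
    params: SsrPrimerParams,
    centered_first: bool,
) -> Iterator[tuple[int, int]]:
    """Yield (forward_start, reverse_end) 1-based placements in ranked order."""
    target_len = target_end - target_start + 1

    def margins_for(product: int, offset: int) -> list[int]:
        total = product - target_len  # left margin + right margin
        out = []
        for m_left in ((total + offset) // 2, (total - offset) // 2):
            # parity check: both margins must be non-negative ints with the
            # requested imbalance
            if abs((total - m_left) - m_left) == offset and 0 <= m_left <= total:
                out.append(m_left)
        # larger left margin first => leftmost forward start first
        return sorted(set(out), reverse=True)

    sizes = range(max(params.min_amplicon, target_len), params.max_amplicon + 1)
    if centered_first:
        max_off = params.max_amplicon
        for offset in range(0, max_off + 1):
            for product in sizes:
                for m_left in margins_for(product, offset):
                    f_start = target_start - m_left
                    r_end = target_end + (product - target_len - m_left)
                    if f_start >= 1 and r_end <= seq_len:
                        yield f_start, r_end
    else:
        for product in sizes:
            total = product - target_len
            for offset in range(0, total + 1):
                for m_left in margins_for(product, offset):
                    f_start = target_start - m_left
                    r_end = target_end + (total - m_left)
                    if f_start >= 1 and r_end <= seq_len:
                        yield f_start, r_end


def design_primer_pair(
    sequence: str,
    target_start: int,
    target_end: int,
    params: SsrPrimerParams | None = None,
    centered_first: bool = False,
) -> PrimerPair | PrimerRejection:
    """Deterministically design one primer pair bracketing a target interval.

    Returns a :class:`PrimerPair` or a :class:`PrimerRejection` naming the
    constraint that excluded the most candidate placements (``SPACE``,
    ``GC`` or ``TM``).
    """
    params = params or SsrPrimerParams()
    n = len(sequence)
    if not 1 <= target_start <= target_end <= n:
        raise ValueError(f"target {target_start}-{target_end} outside sequence of length {n}")
    gc_prefix = [0] * (n + 1)
    for i, c in enumerate(sequence.upper()):
        gc_prefix[i + 1] = gc_prefix[i] + (c in "GC")
    fwd = _SideTable(gc_prefix, params, forward=True)
    rev = _SideTable(gc_prefix, params, forward=False)
    fail_counts: dict[str, int] = {}
    any_placement = False
    for f_start, r_end in _placements(target_start, target_end, n, params, centered_first):
        any_placement = True
        f_len, f_why = fwd.min_len(f_start - 1, target_start - f_start)
        if f_len is None:
            fail_counts[f_why] = fail_counts.get(f_why, 0) + 1
            continue
        r_len, r_why = rev.min_len(r_end - 1, r_end - target_end)
        if r_len is None:
            fail_counts[r_why] = fail_counts.get(r_why, 0) + 1
            continue
        forward_seq = sequence[f_start - 1 : f_start - 1 + f_len]
        reverse_window = sequence[r_end - r_len : r_end]
        return PrimerPair(
            forward_seq=forward_seq,
            forward_start=f_start,
            reverse_seq=reverse_complement(reverse_window),
            reverse_end=r_end,
        )
    if not any_placement:
        return PrimerRejection(constraint="SPACE")
    blocking = max(fail_counts, key=lambda k: (fail_counts[k], k)) if fail_counts else "SPACE"
    return PrimerRejection(constraint=blocking)
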