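"""Post-merge read filtering: primer check/trim, length floor, singleton removal.

Merged amplicon reads are filtered in three stages — drop reads with corrupt
primers, drop merged reads shorter than the configured floor (290 bp by
default, matching a 307 bp primered amplicon), and drop sequences occurring
only once within an individual — then collapsed and ranked from most to least
frequent.  Retained sequences have their primers removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Union

from .core import reverse_complement
from .simulate import ReadRecord

__all__ = [
    "RankedVariantTable",
    "filter_merged_reads",
    "reverse_complement_normalize",
]

Reads = Iterable[Union[str, ReadRecord, tuple]]

DEFAULT_MIN_LEN = 290


def _as_counts(reads: Reads) -> Counter:
    counts: Counter = Counter()
    for r in reads:
        if isinstance(r, str):
            counts[r] += 1
        elif isinstance(r, ReadRecord):
            counts[r.seq] += r.count
        else:
            seq, n = r[0], r[1]
            counts[seq] += int(n)
    return counts


@dataclass
class RankedVariantTable:
    """Per-individual tally of distinct merged-read sequences, count-ranked."""

    individual_id: str
    rows: list[tuple[str, int]] = field(default_factory=list)  # (sequence, count), rank = index + 1
    stage_counts: dict[str, int] = field(default_factory=dict)
    locus: str = ""

    def __post_init__(self) -> None:
        for _, c in self.rows:
            if c <= 0:
                raise ValueError("variant counts must be strictly positive")
        self.rows.sort(key=lambda r: (-r[1], r[0]))

    @property
    def sequences(self) -> list[str]:
        return [s for s, _ in self.rows]

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.rows]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def __len__(self) -> int:
        return len(self.rows)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _starts_with(seq: str, primer: str, k: int) -> bool:
    return len(seq) >= len(primer) and _mismatches(seq[: len(primer)], primer) <= k


def reverse_complement_normalize(
    reads: Reads,
    fwd_primer: str,
    max_mismatch: int = 0,
) -> list[tuple[str, int]]:
    """Orient merged reads so that any read carrying the forward primer (in
    either orientation) begins with it.  Reads lacking the primer in both
    orientations pass through unchanged (and are later dropped as corrupt)."""
    out: list[tuple[str, int]] = []
    for seq, n in _as_counts(reads).items():
        if _starts_with(seq, fwd_primer, max_mismatch):
            out.append((seq, n))
        else:
            rc = reverse_complement(seq)
            out.append((rc, n) if _starts_with(rc, fwd_primer, max_mismatch) else (seq, n))
    return out


def filter_merged_reads(
    reads: Reads,
    fwd_primer: str,
    rev_primer: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_mismatch: int = 0,
    individual_id: str = "",
    locus: str = "",
) -> RankedVariantTable:
    """Apply the post-merge filters in order (primer -> length -> singleton)
    and return the primer-trimmed, count-ranked variant table.

    "Corrupt primers" means either primer absent at its expected terminus with
    more than ``max_mismatch`` mismatches (strict by default).  The length
    floor applies to the merged read *before* primer trimming.  Singleton
    removal applies after exact-sequence collapsing, within the individual.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if min_len <= len(fwd_primer) + len(rev_primer):
        raise ValueError("min_len must exceed the combined primer length")

    rev_rc = reverse_complement(rev_primer)
    oriented = reverse_complement_normalize(reads, fwd_primer, max_mismatch)
    n_input = sum(n for _, n in oriented)

    with_primers: Counter = Counter()
    for seq, n in oriented:
        if (
            len(seq) >= len(fwd_primer) + len(rev_primer)
            and _starts_with(seq, fwd_primer, max_mismatch)
            and _mismatches(seq[-len(rev_rc):], rev_rc) <= max_mismatch
        ):
            with_primers[seq] += n
    n_primer_ok = sum(with_primers.values())

    long_enough: Counter = Counter()
    for seq, n in with_primers.items():
        if len(seq) >= min_len:
            long_enough[seq] += n
    n_len_ok = sum(long_enough.values())

    trimmed: Counter = Counter()
    for seq, n in long_enough.items():
        trimmed[seq[len(fwd_primer): len(seq) - len(rev_rc)]] += n

    kept = {s: n for s, n in trimmed.items() if n >= 2}
    n_final = sum(kept.values())

    return RankedVariantTable(
        individual_id=individual_id,
        locus=locus,
        rows=sorted(kept.items(), key=lambda r: (-r[1], r[0])),
        stage_counts={
            "input": n_input,
            "after_primer": n_primer_ok,
            "after_length": n_len_ok,
            "after_singleton": n_final,
            "dropped_primer": n_input - n_primer_ok,
            "dropped_length": n_primer_ok - n_len_ok,
            "dropped_singleton": n_len_ok - n_final,
        },
    )
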