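"""The One-SNP-Away scan.

Find the codons of a coding sequence that can be converted to a codon for a
given target residue — or to a stop codon — by exactly one nucleotide
substitution, and count such positions inside residue windows.

A position counts once no matter how many distinct substitutions reach the
target there: the scan counts *positions*, not substitutions. Codons that
already encode the target are by default not reported ("one step away", not
"zero steps away"); pass ``exclude_current=False`` to include them with their
reachable substitutions anyway.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .seqcore import (
    GeneticCode,
    CodingSequence,
    PointSubstitution,
    NUCLEOTIDES,
    STOP,
    STOP_NAMES,
    normalize_target,
    standard_code,
)


@dataclass(frozen=True)
class ScanOptions:
    """Options for :func:`scan_one_snp_away`.

    ``start``/``stop`` bound the scanned codon range (1-based, inclusive);
    ``stop=None`` means the last sense codon. The terminal stop codon is
    never scanned.
    """

    exclude_current: bool = True
    start: int = 1
    stop: int | None = None


@dataclass(frozen=True)
class AccessibilityHit:
    """One codon with >=1 single-base route to the target."""

    codon_index: int
    ref_codon: str
    ref_aa: str
    target: str
    substitutions: tuple[PointSubstitution, ...]

    def __post_init__(self) -> None:
        if not self.substitutions:
            raise ValueError("an accessibility hit must carry >=1 substitution")


@dataclass(frozen=True)
class AccessibilityReport:
    """Deterministic, position-sorted result of one scan."""

    sequence_id: str
    target: str
    options: ScanOptions
    hits: tuple[AccessibilityHit, ...] = field(default_factory=tuple)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(h.codon_index for h in self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def accessible_substitutions(
    codon: str,
    target: str,
    code: GeneticCode | None = None,
    *,
    exclude_current: bool = True,
    codon_index: int = 1,
) -> list[PointSubstitution]:
    """Every single-base change converting ``codon`` into a codon for ``target``.

    Returns an empty list if no single change suffices, or — by convention —
    if the codon already encodes the target and ``exclude_current`` is set.
    Results are sorted by (offset, alt_base).
    """
    code = code or standard_code()
    target = normalize_target(target)
    if exclude_current and code.amino_acid(codon) == target:
        return []
    out = []
    for off in (1, 2, 3):
        ref = codon[off - 1]
        for alt in NUCLEOTIDES:
            if alt == ref:
                continue
            product = codon[: off - 1] + alt + codon[off:]
            if code.amino_acid(product) == target:
                out.append(PointSubstitution(codon_index, off, ref, alt))
    return out


def scan_one_snp_away(
    cds: CodingSequence,
    target: str,
    options: ScanOptions | None = None,
    code: GeneticCode | None = None,
) -> AccessibilityReport:
    """Scan the sense codons of ``cds`` for positions one substitution from ``target``."""
    code = code or standard_code()
    options = options or ScanOptions()
    target = normalize_target(target)
    last = cds.sense_codon_count
    stop = last if options.stop is None else options.stop
    if not (1 <= options.start <= stop <= last):
        raise ValueError(
            f"{cds.id}: empty or out-of-range scan window {options.start}..{stop} "
            f"(sense codons 1..{last})"
        )
    hits = []
    for i in range(options.start, stop + 1):
        codon = cds.codon(i)
        subs = accessible_substitutions(
            codon, target, code, exclude_current=options.exclude_current, codon_index=i
        )
        if subs:
            hits.append(
                AccessibilityHit(
                    codon_index=i,
                    ref_codon=codon,
                    ref_aa=code.amino_acid(codon),
                    target=target,
                    substitutions=tuple(subs),
                )
            )
    return AccessibilityReport(
        sequence_id=cds.id, target=target, options=options, hits=tuple(hits)
    )


def count_accessible_in_ranges(
    report: AccessibilityReport,
    ranges: list[tuple[int, int]],
) -> list[int]:
    """Count hit *positions* of ``report`` inside each inclusive residue interval.

    Intervals may overlap each other; each must lie within the scanned span.
    """
    scanned_start = report.options.start
    scanned_stop = report.options.stop
    positions = report.positions
    counts = []
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"reversed interval {lo}..{hi}")
        if lo < scanned_start or (scanned_stop is not None and hi > scanned_stop):
            raise ValueError(
                f"interval {lo}..{hi} outside scanned span "
                f"{scanned_start}..{scanned_stop if scanned_stop is not None else 'end'}"
            )
        counts.append(sum(lo <= p <= hi for p in positions))
    return counts


def report_to_tsv(report: AccessibilityReport, header_comment: str | None = None) -> str:
    """Serialize a report to the TSV interchange format.

    Columns: seq_id, codon_index, ref_codon, ref_aa, target, n_substitutions,
    substitutions (semicolon-joined ``offset:ref>alt->codon``).
    """
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write("seq_id\tcodon_index\tref_codon\tref_aa\ttarget\tn_substitutions\tsubstitutions\n")
    target_label = "STOP" if report.target == STOP else report.target
    for hit in report.hits:
        subs = ";".join(
            f"{s.offset}:{s.ref_base}>{s.alt_base}->"
            f"{hit.ref_codon[: s.offset - 1] + s.alt_base + hit.ref_codon[s.offset :]}"
            for s in hit.substitutions
        )
        buf.write(
            f"{report.sequence_id}\t{hit.codon_index}\t{hit.ref_codon}\t{hit.ref_aa}\t"
            f"{target_label}\t{len(hit.substitutions)}\t{subs}\n"
        )
    return buf.getvalue()


def stop_scan_summary(report: AccessibilityReport) -> dict[str, int]:
    """Per-stop-name position counts for a STOP-target report (positions may
    be reachable as more than one stop type, so counts can overlap)."""
    if report.target != STOP:
        raise ValueError("stop_scan_summary requires a STOP-target report")
    counts = {name: 0 for name in set(STOP_NAMES.values())}
    for hit in report.hits:
        names = set()
        for s in hit.substitutions:
            product = hit.ref_codon[: s.offset - 1] + s.alt_base + hit.ref_codon[s.offset :]
            names.add(STOP_NAMES[product])
        for n in names:
            counts[n] += 1
    return counts
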