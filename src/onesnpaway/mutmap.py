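"""Mutant-allele tables, domain maps, and mutational bookkeeping.

Ingests tables of single-codon mutant alleles (one row per allele, in the
TSV dialect described in :func:`parse_mutation_table`), summarizes them
against named domain maps, does saturation accounting under a uniform-draw
coverage model, assigns coiled-coil heptad registers, and renders plain-text
per-residue mutational maps.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    CodingSequence,
    GeneticCode,
    STOP,
    STOP_NAMES,
    standard_code,
)
from .snapaway import AccessibilityReport, accessible_substitutions

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
HEPTAD_LETTERS = "abcdefg"

LYSIS_DEFECTIVE = "defective"
LYSIS_FUNCTIONAL = "functional"
SOURCE_RANDOM = "random"
SOURCE_SITE_DIRECTED = "site_directed"

_STOP_NAME_SET = set(STOP_NAMES.values())


@dataclass(frozen=True)
class MutationRecord:
    """One allele row: a substitution, nonsense change, or engineered replacement.

    ``alt`` is an amino-acid letter, :data:`STOP` (with ``stop_name`` set), or
    ``None`` for an engineered replacement carrying ``replacement_label``.
    ``isolates`` is 0 exactly for site-directed alleles.
    """

    gene: str
    codon_position: int
    ref_aa: str
    alt: str | None
    isolates: int
    lysis: str
    source: str
    stop_name: str | None = None
    replacement_label: str | None = None
    change_type: str | None = None  # optional transcribed ts/tv cross-check

    def __post_init__(self) -> None:
        if self.codon_position < 1:
            raise ValueError(f"codon position {self.codon_position} must be >= 1")
        if self.isolates < 0:
            raise ValueError(f"negative isolate count {self.isolates}")
        if (self.isolates == 0) != (self.source == SOURCE_SITE_DIRECTED):
            raise ValueError(
                f"{self.gene} position {self.codon_position}: isolates must be 0 "
                "iff the allele is site-directed"
            )
        if self.lysis not in (LYSIS_DEFECTIVE, LYSIS_FUNCTIONAL):
            raise ValueError(f"bad lysis phenotype {self.lysis!r}")
        if self.alt is None and not self.replacement_label:
            raise ValueError("replacement records need a replacement_label")
        if self.alt == STOP and self.stop_name not in _STOP_NAME_SET:
            raise ValueError(f"nonsense record needs a stop name, got {self.stop_name!r}")

    @property
    def is_replacement(self) -> bool:
        return self.alt is None

    @property
    def is_nonsense(self) -> bool:
        return self.alt == STOP

    @property
    def is_missense(self) -> bool:
        """Amino-acid substitution (start-loss changes like Met1Lys included)."""
        return self.alt is not None and self.alt != STOP and self.alt != self.ref_aa


@dataclass(frozen=True)
class DomainMap:
    """Named inclusive residue intervals of one protein."""

    gene: str
    intervals: Mapping[str, tuple[int, int]]
    protein_length: int | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi or lo < 1:
                raise ValueError(f"{self.gene} domain {name}: bad interval {lo}..{hi}")
            if self.protein_length is not None and hi > self.protein_length:
                raise ValueError(
                    f"{self.gene} domain {name}: interval {lo}..{hi} exceeds protein "
                    f"length {self.protein_length}"
                )

    def domain_of(self, position: int) -> str | None:
        for name, (lo, hi) in self.intervals.items():
            if lo <= position <= hi:
                return name
        return None

    @classmethod
    def rz_default(cls) -> "DomainMap":
        """Lambda Rz: N-terminal TMD, two coiled coils, interhelical linker, CTD."""
        return cls(
            gene="Rz",
            protein_length=153,
            intervals={
                "NTMD": (1, 24),
                "CC1": (27, 87),
                "L2": (89, 120),
                "CC2": (121, 150),
                "CTD": (151, 153),
            },
        )

    @classmethod
    def rz1_default(cls) -> "DomainMap":
        """Lambda Rz1: signal sequence, lipoylated Cys anchor, linker, PRR, CTD."""
        return cls(
            gene="Rz1",
            protein_length=60,
            intervals={
                "signal": (1, 19),
                "lipoylated-Cys": (20, 20),
                "linker": (21, 31),
                "PRR": (32, 44),
                "CTD": (45, 60),
            },
        )


def _parse_alt(raw: str, row: int) -> tuple[str | None, str | None, str | None]:
    """Decode the ``alt`` column -> (alt, stop_name, replacement_label)."""
    raw = raw.strip()
    if len(raw) == 1:
        if raw.upper() not in AA_LETTERS:
            raise ValueError(f"row {row}: unknown amino-acid letter {raw!r}")
        return raw.upper(), None, None
    up = raw.upper()
    if up.startswith("X(") or up.startswith("*("):
        if not up.endswith(")"):
            raise ValueError(f"row {row}: malformed stop label {raw!r}")
        name = up[2:-1].lower()
        if name not in _STOP_NAME_SET:
            raise ValueError(
                f"row {row}: unknown stop type {raw!r} (expected amber/ochre/opal)"
            )
        return STOP, name, None
    # anything longer is an engineered-replacement label (artificial TMD,
    # Gly-Ser linker, ...)
    return None, None, raw


def parse_mutation_table(path_or_buffer) -> list[MutationRecord]:
    """Parse the mutant-allele TSV dialect into typed records.

    Tab-separated, UTF-8, ``#`` comment lines, header row required with
    columns ``gene, codon_position, ref_aa, alt, isolates, lysis, source``
    and optionally ``change_type``. ``alt`` is a single amino-acid letter,
    ``X(Amber|Ochre|Opal)`` for nonsense alleles, or a free-text
    engineered-replacement label.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", comment="#", dtype=str).fillna("")
    required = ["gene", "codon_position", "ref_aa", "alt", "isolates", "lysis", "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing column(s): {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1  # 1-based data-row number
        try:
            position = int(row["codon_position"])
            isolates = int(row["isolates"])
        except ValueError as exc:
            raise ValueError(f"row {rownum}: non-integer position/isolates") from exc
        if isolates < 0:
            raise ValueError(f"row {rownum}: negative isolate count {isolates}")
        ref_aa = row["ref_aa"].strip().upper()
        if ref_aa not in AA_LETTERS:
            raise ValueError(f"row {rownum}: unknown amino-acid letter {row['ref_aa']!r}")
        alt, stop_name, label = _parse_alt(row["alt"], rownum)
        change_type = row.get("change_type", "").strip().lower() or None
        if change_type not in (None, "transition", "transversion"):
            raise ValueError(f"row {rownum}: bad change_type {change_type!r}")
        try:
            records.append(
                MutationRecord(
                    gene=row["gene"].strip(),
                    codon_position=position,
                    ref_aa=ref_aa,
                    alt=alt,
                    isolates=isolates,
                    lysis=row["lysis"].strip().lower(),
                    source=row["source"].strip().lower(),
                    stop_name=stop_name,
                    replacement_label=label,
                    change_type=change_type,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from exc
    return records


@dataclass(frozen=True)
class DomainTally:
    missense_alleles: int = 0
    missense_positions: int = 0
    nonsense_alleles: int = 0
    nonsense_positions: int = 0


@dataclass(frozen=True)
class MutationSummary:
    """Deterministic per-gene tallies over a record list.

    Allele sums count isolates of random-mutagenesis records (isolates >= 1);
    position counts are of distinct codon positions. Start-loss changes that
    alter the residue (e.g. Met1Lys) count as missense; engineered
    replacements are excluded throughout.
    """

    gene: str
    missense_isolate_sum: int
    missense_positions: int
    nonsense_isolate_sum: int
    nonsense_positions: int
    per_domain: Mapping[str, DomainTally]
    ts_fraction: float | None = None
    tv_fraction: float | None = None
    n_classified: int = 0


def _random_records(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    return [r for r in records if r.source == SOURCE_RANDOM and r.isolates >= 1]


def distinct_missense_positions(
    records: Iterable[MutationRecord],
    min_position: int = 1,
    max_position: int | None = None,
) -> set[int]:
    """Distinct positions of random-source missense alleles within a window."""
    return {
        r.codon_position
        for r in _random_records(records)
        if r.is_missense
        and r.codon_position >= min_position
        and (max_position is None or r.codon_position <= max_position)
    }


def recompute_change_types(
    records: Iterable[MutationRecord],
    cds: CodingSequence,
    code: GeneticCode | None = None,
) -> dict[int, str | None]:
    """Re-derive ts/tv per record index from the CDS codons.

    For each substitution record the single-base changes of the reference
    codon reaching the recorded alternative residue (or the named stop) are
    enumerated; when they all share one mutation type that type is returned,
    otherwise ``None`` (ambiguous). Replacement records map to ``None``.
    """
    from .seqcore import classify_substitution

    code = code or standard_code()
    out: dict[int, str | None] = {}
    for i, rec in enumerate(records):
        if rec.is_replacement:
            out[i] = None
            continue
        codon = cds.codon(rec.codon_position)
        if code.amino_acid(codon) != rec.ref_aa:
            raise ValueError(
                f"{rec.gene} position {rec.codon_position}: CDS codon {codon} encodes "
                f"{code.amino_acid(codon)}, record says {rec.ref_aa}"
            )
        subs = accessible_substitutions(
            codon, rec.alt, code, exclude_current=True, codon_index=rec.codon_position
        )
        if rec.is_nonsense:
            subs = [
                s
                for s in subs
                if STOP_NAMES[codon[: s.offset - 1] + s.alt_base + codon[s.offset :]]
                == rec.stop_name
            ]
        types = {classify_substitution(s.ref_base, s.alt_base) for s in subs}
        out[i] = types.pop() if len(types) == 1 else None
    return out


def summarize_mutations(
    records: Sequence[MutationRecord],
    domain_map: DomainMap,
    cds: CodingSequence | None = None,
    code: GeneticCode | None = None,
) -> MutationSummary:
    """Summarize one gene's records against its domain map.

    When ``cds`` is supplied, transition/transversion proportions are
    recomputed from the codons (records whose ts/tv status is ambiguous from
    the amino-acid change alone are left out of the denominator).
    """
    genes = {r.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    if genes and domain_map.gene not in genes:
        raise ValueError(
            f"domain map is for {domain_map.gene!r} but records are for {genes.pop()!r}"
        )
    rand = _random_records(records)
    missense = [r for r in rand if r.is_missense]
    nonsense = [r for r in rand if r.is_nonsense]

    per_domain: dict[str, DomainTally] = {}
    for name, (lo, hi) in domain_map.intervals.items():
        mis = [r for r in missense if lo <= r.codon_position <= hi]
        non = [r for r in nonsense if lo <= r.codon_position <= hi]
        per_domain[name] = DomainTally(
            missense_alleles=sum(r.isolates for r in mis),
            missense_positions=len({r.codon_position for r in mis}),
            nonsense_alleles=sum(r.isolates for r in non),
            nonsense_positions=len({r.codon_position for r in non}),
        )

    ts_fraction = tv_fraction = None
    n_classified = 0
    if cds is not None:
        kinds = recompute_change_types(records, cds, code)
        counts = {"transition": 0, "transversion": 0}
        for i, rec in enumerate(records):
            k = kinds.get(i)
            if k is not None and rec.source == SOURCE_RANDOM and rec.isolates >= 1:
                counts[k] += rec.isolates
        n_classified = counts["transition"] + counts["transversion"]
        if n_classified:
            ts_fraction = counts["transition"] / n_classified
            tv_fraction = counts["transversion"] / n_classified

    return MutationSummary(
        gene=domain_map.gene,
        missense_isolate_sum=sum(r.isolates for r in missense),
        missense_positions=len({r.codon_position for r in missense}),
        nonsense_isolate_sum=sum(r.isolates for r in nonsense),
        nonsense_positions=len({r.codon_position for r in nonsense}),
        per_domain=per_domain,
        ts_fraction=ts_fraction,
        tv_fraction=tv_fraction,
        n_classified=n_classified,
    )


@dataclass(frozen=True)
class SaturationSummary:
    """Coverage of the mutationally accessible positions.

    ``expected_coverage(n)`` is the expected number of distinct positions hit
    after ``n`` uniform independent draws over ``accessible`` positions:
    ``m * (1 - (1 - 1/m)**n)`` — the coupon-collector expectation.
    """

    accessible: int
    observed: int

    @property
    def fraction(self) -> float:
        return self.observed / self.accessible

    def expected_coverage(self, n_draws: int) -> float:
        if n_draws < 0:
            raise ValueError("n_draws must be >= 0")
        m = self.accessible
        return m * (1.0 - (1.0 - 1.0 / m) ** n_draws)

    def simulate_coverage(self, n_draws: int, n_reps: int, seed: int = 0) -> tuple[float, float]:
        """Monte-Carlo (mean, standard error) of distinct positions after draws."""
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, self.accessible, size=(n_reps, n_draws))
        distinct = np.array([len(np.unique(row)) for row in draws], dtype=float)
        return float(distinct.mean()), float(distinct.std(ddof=1) / math.sqrt(n_reps))


def saturation_summary(
    observed_positions: Iterable[int],
    accessible_positions: Iterable[int],
) -> SaturationSummary:
    """Build a :class:`SaturationSummary`; observed must be ⊆ accessible."""
    observed = set(observed_positions)
    accessible = set(accessible_positions)
    if not accessible:
        raise ValueError("no accessible positions")
    stray = sorted(observed - accessible)
    if stray:
        raise ValueError(f"observed positions not accessible: {stray}")
    return SaturationSummary(accessible=len(accessible), observed=len(observed))


@dataclass(frozen=True)
class HeptadAssignment:
    """A coiled-coil abcdefg register over an inclusive residue range.

    ``anchor`` is a residue index assigned letter 'a'; it need not lie inside
    the range (any index congruent mod 7 gives the same register).
    """

    start: int
    end: int
    anchor: int

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad heptad range {self.start}..{self.end}")
        if self.anchor < 1:
            raise ValueError("anchor must be a positive residue index")

    def letter(self, position: int) -> str:
        return HEPTAD_LETTERS[(position - self.anchor) % 7]

    @property
    def letters(self) -> dict[int, str]:
        return {i: self.letter(i) for i in range(self.start, self.end + 1)}


def heptad_positions(
    assignment: HeptadAssignment, letters_wanted: Iterable[str]
) -> list[int]:
    """Ascending residue positions in the range whose heptad letter is wanted."""
    wanted = set(letters_wanted)
    if not wanted:
        raise ValueError("empty heptad letter set")
    bad = wanted - set(HEPTAD_LETTERS)
    if bad:
        raise ValueError(f"not heptad letters: {sorted(bad)}")
    return [
        i for i in range(assignment.start, assignment.end + 1) if assignment.letter(i) in wanted
    ]


def span_estimate(n_residues: int, rise_per_residue_nm: float = 0.15) -> float:
    """Helical end-to-end length in nm: residues x rise per residue (default 0.15 nm)."""
    if n_residues < 0:
        raise ValueError("residue count must be >= 0")
    if rise_per_residue_nm < 0:
        raise ValueError("rise per residue must be >= 0")
    return n_residues * rise_per_residue_nm


def render_mutation_map(
    records: Sequence[MutationRecord],
    protein: str,
    domain_map: DomainMap,
    accessibility_report: AccessibilityReport | None = None,
    width: int = 60,
) -> tuple[str, str]:
    """Render a fixed-width text map and its TSV twin.

    Per block of ``width`` residues: stacked mutant glyphs (alt residue
    letter, ``*`` for nonsense) above the sequence line, a domain line (first
    letter of the domain name), and an accessibility line (``#`` under
    positions accessible per the report). Engineered replacements are not
    drawn. The TSV twin has one row per residue.
    """
    n = len(protein)
    stacks: dict[int, list[str]] = {}
    for rec in records:
        if rec.is_replacement:
            continue
        if rec.codon_position > n:
            raise ValueError(
                f"record at position {rec.codon_position} beyond protein length {n}"
            )
        glyph = STOP if rec.is_nonsense else rec.alt
        stacks.setdefault(rec.codon_position, []).append(glyph)
    accessible = set(accessibility_report.positions) if accessibility_report else set()

    lines: list[str] = []
    for block_start in range(1, n + 1, width):
        block_end = min(block_start + width - 1, n)
        cols = range(block_start, block_end + 1)
        depth = max((len(stacks.get(i, [])) for i in cols), default=0)
        for level in range(depth - 1, -1, -1):
            lines.append(
                "".join(
                    stacks[i][level] if i in stacks and len(stacks[i]) > level else " "
                    for i in cols
                ).rstrip()
            )
        lines.append("".join(protein[i - 1] for i in cols))
        lines.append(
            "".join((domain_map.domain_of(i) or ".")[0] for i in cols)
        )
        if accessibility_report is not None:
            lines.append("".join("#" if i in accessible else " " for i in cols).rstrip())
        lines.append(f"{block_start:<6d}{'':{max(0, block_end - block_start - 11)}}{block_end:>6d}")
        lines.append("")
    text = "\n".join(lines)

    buf = io.StringIO()
    buf.write("position\taa\tdomain\tn_alleles\talleles\taccessible\n")
    for i in range(1, n + 1):
        alleles = ";".join(stacks.get(i, []))
        buf.write(
            f"{i}\t{protein[i - 1]}\t{domain_map.domain_of(i) or ''}\t"
            f"{len(stacks.get(i, []))}\t{alleles}\t{int(i in accessible)}\n"
        )
    return text, buf.getvalue()
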