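"""Private-allele SNP panel design and validation.

A *private allele* is a homozygous SNP genotype carried by exactly one
cultivar in a set of clonally propagated cultivars.  A locus with such an
allele is diagnostic: detecting the alternative (ALT) base in a pollen
sample proves that pollen of the target cultivar — or of a heterozygous
carrier of the same base — is present.  This module ingests a
cultivar-by-locus diploid genotype table, discovers the private-allele
panel, groups loci by extension base for single-base-extension
multiplexing, and validates that every cultivar remains identifiable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PanelLocus",
    "PanelDesign",
    "PanelValidation",
    "GenotypeParseError",
    "read_genotype_table",
    "builtin_genotype_table",
    "find_private_alleles",
    "multiplex_groups",
    "validate_panel",
    "export_panel",
]

BASES = ("A", "C", "G", "T")

#: Sentinel for an untyped ("NA") genotype call.
MISSING = None

_GENOTYPE_RE = re.compile(r"^[ACGT]{2}$")


class GenotypeParseError(ValueError):
    """Raised when a genotype table cell or header cannot be parsed."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid genotype calls for a set of cultivars at a set of SNP loci.

    Genotypes are unordered allele pairs stored as sorted 2-tuples, e.g.
    ``("G", "T")`` for either "GT" or "TG"; missing calls are ``None``.
    """

    cultivars: tuple[str, ...]
    loci: tuple[str, ...]
    genotypes: dict[tuple[str, str], tuple[str, str] | None]

    def __post_init__(self) -> None:
        if len(set(self.cultivars)) != len(self.cultivars):
            raise GenotypeParseError("duplicate cultivar names")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeParseError("duplicate locus ids")
        if len(self.cultivars) < 2:
            raise GenotypeParseError("need at least 2 cultivars")

    def genotype(self, cultivar: str, locus: str) -> tuple[str, str] | None:
        return self.genotypes[(locus, cultivar)]

    def allele_count(self, cultivar: str, locus: str, base: str) -> int:
        """Number of copies of ``base`` (0-2) carried; 0 for MISSING."""
        g = self.genotypes[(locus, cultivar)]
        if g is MISSING:
            return 0
        return sum(1 for a in g if a == base)

    def subset(self, cultivars=None, loci=None) -> "GenotypeMatrix":
        cultivars = tuple(cultivars) if cultivars is not None else self.cultivars
        loci = tuple(loci) if loci is not None else self.loci
        gt = {(l, c): self.genotypes[(l, c)] for l in loci for c in cultivars}
        return GenotypeMatrix(cultivars, loci, gt)


@dataclass(frozen=True)
class PanelLocus:
    """One diagnostic locus of a private-allele panel.

    ``alt_base`` is homozygous in exactly one cultivar (``target_cultivar``);
    ``het_carrier_set`` lists cultivars carrying exactly one ALT copy, whose
    pollen also fires the ALT extension assay (at half dosage);
    ``missing_set`` lists cultivars whose genotype is unknown here and whose
    ALT status is therefore unknown; ``anomalous_set`` lists cultivars
    carrying an allele outside {REF, ALT} as printed in the source table.
    """

    locus_id: str
    ref_base: str
    alt_base: str
    target_cultivar: str
    het_carrier_set: frozenset[str]
    missing_set: frozenset[str]
    anomalous_set: frozenset[str] = frozenset()

    @property
    def hom_alt_set(self) -> frozenset[str]:
        return frozenset({self.target_cultivar})

    @property
    def candidate_carriers(self) -> frozenset[str]:
        """Cultivars whose pollen could fire the ALT assay at this locus."""
        return self.hom_alt_set | self.het_carrier_set | self.missing_set

    @property
    def flagged(self) -> bool:
        return bool(self.missing_set or self.anomalous_set)


@dataclass
class PanelDesign:
    """A validated set of diagnostic loci plus multiplex grouping."""

    loci: list[PanelLocus]
    cultivars: tuple[str, ...]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (locus, reason)
    multiplex_groups_alt: dict[str, frozenset[str]] = field(default_factory=dict)
    multiplex_groups_ref: dict[str, frozenset[str]] = field(default_factory=dict)

    def locus(self, locus_id: str) -> PanelLocus:
        for pl in self.loci:
            if pl.locus_id == locus_id:
                return pl
        raise KeyError(f"locus {locus_id!r} not in panel")

    @property
    def locus_ids(self) -> list[str]:
        return [pl.locus_id for pl in self.loci]

    @property
    def cultivar_to_loci(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pl in self.loci:
            out.setdefault(pl.target_cultivar, []).append(pl.locus_id)
        return out


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a cultivar x locus genotype table (CSV or TSV, auto-detected).

    One locus per row; first column is the locus id, remaining columns are
    cultivars.  Cells are two-letter genotypes from {A,C,G,T} ("GT" == "TG")
    or "NA" for an untyped call.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise GenotypeParseError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        cultivars = tuple(h.strip() for h in header[1:])
        loci: list[str] = []
        genotypes: dict[tuple[str, str], tuple[str, str] | None] = {}
        for row_no, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            locus = row[0].strip().replace(" ", "")
            if locus in loci:
                raise GenotypeParseError(f"{path}:{row_no}: duplicate locus id {locus!r}")
            if len(row) != len(cultivars) + 1:
                raise GenotypeParseError(
                    f"{path}:{row_no}: expected {len(cultivars) + 1} columns, got {len(row)}"
                )
            for cultivar, cell in zip(cultivars, row[1:]):
                cell = cell.strip().upper()
                if cell in {"NA", ""}:
                    genotypes[(locus, cultivar)] = MISSING
                elif _GENOTYPE_RE.match(cell):
                    genotypes[(locus, cultivar)] = tuple(sorted(cell))  # type: ignore[assignment]
                else:
                    raise GenotypeParseError(
                        f"{path}:{row_no}: malformed genotype {cell!r} "
                        f"for cultivar {cultivar!r} at locus {locus!r}"
                    )
            loci.append(locus)
    return GenotypeMatrix(cultivars, tuple(loci), genotypes)


def builtin_genotype_table() -> GenotypeMatrix:
    """The packaged 12-cultivar macadamia genotype table (18 SNP loci)."""
    ref = resources.files("pollenflow") / "data" / "table1_genotypes.tsv"
    with resources.as_file(ref) as path:
        return read_genotype_table(path)


def _discover_locus(gm: GenotypeMatrix, locus: str) -> PanelLocus | tuple[str, str]:
    """Classify one locus; returns a PanelLocus or (locus, exclusion reason)."""
    hom: dict[str, list[str]] = {b: [] for b in BASES}
    typed = []
    for c in gm.cultivars:
        g = gm.genotype(c, locus)
        if g is MISSING:
            continue
        typed.append(c)
        if g[0] == g[1]:
            hom[g[0]].append(c)
    if not typed:
        return (locus, "all genotypes missing")
    candidates = [b for b in BASES if len(hom[b]) == 1]
    if not candidates:
        return (locus, "no base homozygous in exactly one cultivar")
    if len(candidates) > 1:
        return (locus, "non-unique diagnostic: multiple sole-homozygous bases "
                       + "/".join(candidates))
    alt = candidates[0]
    target = hom[alt][0]
    # REF: the predominant base — most homozygous carriers, then most copies.
    others = [b for b in BASES if b != alt]
    def ref_key(b: str):
        copies = sum(gm.allele_count(c, locus, b) for c in gm.cultivars)
        return (len(hom[b]), copies)
    ref = max(others, key=ref_key)
    if ref_key(ref) == (0, 0):
        return (locus, "no reference base among remaining cultivars")
    het, missing, anomalous = set(), set(), set()
    for c in gm.cultivars:
        g = gm.genotype(c, locus)
        if g is MISSING:
            missing.add(c)
            continue
        if gm.allele_count(c, locus, alt) == 1:
            het.add(c)
        if c != target and any(a not in (ref, alt) for a in g):
            anomalous.add(c)
    return PanelLocus(
        locus_id=locus,
        ref_base=ref,
        alt_base=alt,
        target_cultivar=target,
        het_carrier_set=frozenset(het),
        missing_set=frozenset(missing),
        anomalous_set=frozenset(anomalous),
    )


def find_private_alleles(gm: GenotypeMatrix) -> PanelDesign:
    """Derive the private-allele panel from a genotype matrix.

    A locus is diagnostic when exactly one base is homozygous in exactly one
    cultivar; that base is the ALT allele and that cultivar the target.  Loci
    with no such base (monomorphic, or shared homozygotes) or with a
    reciprocal pair of sole-homozygous bases are excluded with a reason.
    Loci with MISSING entries are retained but flagged.
    """
    loci: list[PanelLocus] = []
    excluded: list[tuple[str, str]] = []
    for locus in gm.loci:
        res = _discover_locus(gm, locus)
        if isinstance(res, PanelLocus):
            loci.append(res)
        else:
            excluded.append(res)
    design = PanelDesign(loci=loci, cultivars=gm.cultivars, excluded=excluded)
    return multiplex_groups(design)


def multiplex_groups(design: PanelDesign) -> PanelDesign:
    """Partition panel loci by targeted extension base (ALT) and by REF base.

    Single-base-extension chemistry extends one acyclonucleotide per
    reaction, so loci sharing an extension base can be multiplexed.
    """
    alt: dict[str, set[str]] = {}
    ref: dict[str, set[str]] = {}
    for pl in design.loci:
        alt.setdefault(pl.alt_base, set()).add(pl.locus_id)
        ref.setdefault(pl.ref_base, set()).add(pl.locus_id)
    design.multiplex_groups_alt = {b: frozenset(s) for b, s in sorted(alt.items())}
    design.multiplex_groups_ref = {b: frozenset(s) for b, s in sorted(ref.items())}
    return design


@dataclass
class PanelValidation:
    """Per-cultivar identifiability report for a panel design."""

    passed: bool
    n_loci: int
    loci_per_cultivar: dict[str, list[str]]
    unidentifiable: list[str]
    carrier_warning_loci: dict[str, dict[str, list[str]]]  # locus -> kind -> cultivars
    na_flag_loci: dict[str, list[str]]
    excluded: list[tuple[str, str]]

    def to_text(self) -> str:
        lines = [
            f"panel validation: {'PASS' if self.passed else 'FAIL'}",
            f"diagnostic loci: {self.n_loci}",
            f"cultivars identifiable: "
            f"{len(self.loci_per_cultivar) - len(self.unidentifiable)}"
            f"/{len(self.loci_per_cultivar)}",
        ]
        for cultivar, loci in self.loci_per_cultivar.items():
            mark = "" if loci else "  << NOT IDENTIFIABLE"
            lines.append(f"  {cultivar}: {len(loci)} locus/loci "
                         f"({', '.join(loci) if loci else '-'}){mark}")
        if self.carrier_warning_loci:
            lines.append("carrier warnings (non-target cultivars with a non-REF allele):")
            for locus, kinds in self.carrier_warning_loci.items():
                for kind, cultivars in kinds.items():
                    lines.append(f"  locus {locus}: {kind}: {', '.join(cultivars)}")
        if self.na_flag_loci:
            lines.append("missing-genotype flags:")
            for locus, cultivars in self.na_flag_loci.items():
                lines.append(f"  locus {locus}: NA for {', '.join(cultivars)}")
        for locus, reason in self.excluded:
            lines.append(f"excluded locus {locus}: {reason}")
        return "\n".join(lines)


def validate_panel(design: PanelDesign, gm: GenotypeMatrix) -> PanelValidation:
    """Check that every cultivar in the matrix has >=1 diagnostic locus.

    Also collects, per locus, the confounders that downstream deconvolution
    must know about: heterozygous ALT carriers, alleles outside {REF, ALT}
    as printed, and untyped (NA) cultivars.
    """
    per_cultivar = {c: [] for c in gm.cultivars}
    for pl in design.loci:
        if pl.target_cultivar in per_cultivar:
            per_cultivar[pl.target_cultivar].append(pl.locus_id)
    unidentifiable = [c for c, loci in per_cultivar.items() if not loci]
    warnings: dict[str, dict[str, list[str]]] = {}
    na_flags: dict[str, list[str]] = {}
    for pl in design.loci:
        kinds: dict[str, list[str]] = {}
        if pl.het_carrier_set:
            kinds["het ALT carrier"] = sorted(pl.het_carrier_set)
        if pl.anomalous_set:
            kinds["allele outside {REF,ALT}"] = sorted(pl.anomalous_set)
        if kinds:
            warnings[pl.locus_id] = kinds
        if pl.missing_set:
            na_flags[pl.locus_id] = sorted(pl.missing_set)
    return PanelValidation(
        passed=not unidentifiable,
        n_loci=len(design.loci),
        loci_per_cultivar=per_cultivar,
        unidentifiable=unidentifiable,
        carrier_warning_loci=warnings,
        na_flag_loci=na_flags,
        excluded=list(design.excluded),
    )


def export_panel(design: PanelDesign, path: str | Path, header_lines=()) -> None:
    """Write the panel as CSV (one row per locus)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh)
        w.writerow(["locus_id", "ref", "alt", "target", "het_carriers",
                    "missing", "alt_group", "ref_group"])
        for pl in design.loci:
            w.writerow([
                pl.locus_id, pl.ref_base, pl.alt_base, pl.target_cultivar,
                ";".join(sorted(pl.het_carrier_set)),
                ";".join(sorted(pl.missing_set)),
                pl.alt_base, pl.ref_base,
            ])
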