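"""Mixed-pollen deconvolution from per-locus allele-presence calls.

The ALT-only extension assay reports, per diagnostic locus, whether the
private ALT base was detectable in the pollen DNA washed off a single bee.
Because a locus can fire for its homozygous target cultivar, for
heterozygous carriers of the same base, or (unknowably) for cultivars with
an untyped genotype, recovering the contributing cultivars is a small
exact set-cover problem over at most a dozen cultivars.  This module
solves it exhaustively, separates *confirmed* cultivars from ranked
*ambiguous* alternatives, and scores each bee's capacity to cross-pollinate
the tree it was netted on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .panel import PanelDesign

__all__ = [
    "AlleleCallSet",
    "CultivarPresence",
    "Category",
    "ClassificationResult",
    "interpret_calls",
    "classify_bee",
    "deconvolve_dataset",
    "calls_from_frame",
]

# Dosage quality of an explanation: homozygous ALT (full dose) beats a
# heterozygous carrier (half dose) beats an untyped genotype (unknown dose).
_QUAL_HOM, _QUAL_HET, _QUAL_MISSING = 0, 1, 2


@dataclass(frozen=True)
class AlleleCallSet:
    """Per-locus boolean detections for one bee.

    ``calls`` maps locus id to ``(alt_detected, ref_detected)``;
    ``ref_detected`` may be None when the predominant-allele assay was not
    run (it is carried for confirmation but unused by inference).
    """

    bee_id: str
    calls: dict[str, tuple[bool, bool | None]]

    @property
    def alt_detected(self) -> frozenset[str]:
        return frozenset(l for l, (alt, _) in self.calls.items() if alt)


@dataclass
class CultivarPresence:
    """Deconvolution result for one bee.

    ``confirmed`` are cultivars the calls require; ``ambiguous_alternatives``
    are the minimal-cardinality sets of further cultivars that equally
    explain the remaining detections, best-ranked first; detections with no
    candidate carrier land in ``unexplained_loci``.
    """

    confirmed: frozenset[str]
    ambiguous_alternatives: list[frozenset[str]]
    unexplained_loci: frozenset[str]
    detected_loci: frozenset[str] = frozenset()

    @property
    def top_cover(self) -> frozenset[str]:
        """Best single explanation: confirmed plus the top-ranked alternative."""
        if self.ambiguous_alternatives:
            return self.confirmed | self.ambiguous_alternatives[0]
        return self.confirmed


class Category(str, Enum):
    CROSS_ONLY = "CROSS_ONLY"
    MIXED = "MIXED"
    SELF_ONLY = "SELF_ONLY"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class ClassificationResult:
    category: Category
    score: int | None  # 1 cross-capable, 0 self-only, None undetermined
    cross_cultivars: frozenset[str]


def _cover_quality(cover, loci, candidates, qualities) -> int:
    """Sum over loci of the best dosage quality any cover member offers."""
    total = 0
    for locus in loci:
        total += min(qualities[locus][c] for c in cover if c in candidates[locus])
    return total


def _rank_key(cover, loci, candidates, qualities, full_support):
    return (
        len(cover),
        _cover_quality(cover, loci, candidates, qualities),
        sum(0 if c in full_support else 1 for c in cover),
        tuple(sorted(cover)),
    )


def _minimal_covers(loci, candidates):
    """All minimum-cardinality subsets of cultivars covering ``loci``."""
    universe = sorted(set().union(*(candidates[l] for l in loci)))
    for k in range(1, len(universe) + 1):
        covers = [
            frozenset(combo)
            for combo in itertools.combinations(universe, k)
            if all(any(c in candidates[l] for c in combo) for l in loci)
        ]
        if covers:
            return covers
    return []


def interpret_calls(calls: AlleleCallSet, panel: PanelDesign) -> CultivarPresence:
    """Infer contributing cultivars from ALT-presence calls.

    Confirmation rules:

    * a cultivar that is the *sole* candidate carrier at a detected locus is
      required by that detection;
    * a cultivar all of whose own diagnostic loci are detected is confirmed
      when every way of explaining those loci without it ranks strictly
      worse (larger, or relying on half-dose/unknown-dose carriers).

    Detections left over are covered by exhaustive minimum-cardinality set
    cover; ties rank by fewer cultivars, more homozygous-ALT explanations,
    fuller support among the detections, then cultivar name.
    """
    panel_loci = set(panel.locus_ids)
    unknown = set(calls.calls) - panel_loci
    if unknown:
        raise KeyError(f"calls reference unknown loci: {sorted(unknown)}")

    detected = sorted(calls.alt_detected)
    candidates: dict[str, frozenset[str]] = {}
    qualities: dict[str, dict[str, int]] = {}
    for locus_id in detected:
        pl = panel.locus(locus_id)
        candidates[locus_id] = pl.candidate_carriers
        qualities[locus_id] = {pl.target_cultivar: _QUAL_HOM}
        qualities[locus_id].update({c: _QUAL_HET for c in pl.het_carrier_set})
        qualities[locus_id].update({c: _QUAL_MISSING for c in pl.missing_set})

    unexplained = frozenset(l for l in detected if not candidates[l])
    explainable = [l for l in detected if candidates[l]]
    detected_set = frozenset(detected)

    confirmed: set[str] = set()
    # Sole-candidate confirmations.
    for locus_id in explainable:
        if len(candidates[locus_id]) == 1:
            confirmed.update(candidates[locus_id])
    # Full-signature confirmations: all own loci fired, and no explanation
    # of them without the cultivar is as good as the cultivar itself.
    for cultivar, own_loci in panel.cultivar_to_loci.items():
        if cultivar in confirmed or not own_loci:
            continue
        if not set(own_loci) <= detected_set:
            continue
        own_key = (1, _QUAL_HOM * len(own_loci))  # the cultivar explains all, hom
        rivals = {l: candidates[l] - {cultivar} for l in own_loci}
        if any(not r for r in rivals.values()):
            confirmed.add(cultivar)  # sole candidate somewhere among own loci
            continue
        alt_covers = _minimal_covers(own_loci, rivals)
        best = min(
            ((len(cov), _cover_quality(cov, own_loci, rivals, qualities))
             for cov in alt_covers),
            default=None,
        )
        if best is None or best > own_key:
            confirmed.add(cultivar)

    residual = [
        l for l in explainable if not (candidates[l] & confirmed)
    ]
    alternatives: list[frozenset[str]] = []
    if residual:
        full_support = {
            c for c, own in panel.cultivar_to_loci.items()
            if own and set(own) <= detected_set
        }
        covers = _minimal_covers(residual, candidates)
        covers = [c - confirmed for c in covers]
        alternatives = sorted(
            {c for c in covers if c},
            key=lambda c: _rank_key(c, residual, candidates, qualities, full_support),
        )

    return CultivarPresence(
        confirmed=frozenset(confirmed),
        ambiguous_alternatives=alternatives,
        unexplained_loci=unexplained,
        detected_loci=detected_set,
    )


def classify_bee(
    presence: CultivarPresence,
    host_cultivar: str,
    panel: PanelDesign,
    ambiguity_policy: str = "any_cover_cross",
) -> ClassificationResult:
    """Classify a bee's cross-pollination capability against its host tree.

    Self-pollen is detected when the host cultivar itself is confirmed
    (its own diagnostic loci fired); cross-pollen when any non-host
    cultivar is confirmed or — under the default ``any_cover_cross``
    policy — when every minimal explanation of the remaining detections
    involves a non-host cultivar.  ``confirmed_only`` ignores ambiguous
    covers for scoring.
    """
    if host_cultivar not in panel.cultivars:
        raise KeyError(f"unknown host cultivar {host_cultivar!r}")
    if ambiguity_policy not in {"any_cover_cross", "confirmed_only"}:
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")

    self_detected = host_cultivar in presence.confirmed
    cross_set = presence.confirmed - {host_cultivar}
    cross_detected = bool(cross_set)
    if (
        not cross_detected
        and ambiguity_policy == "any_cover_cross"
        and presence.ambiguous_alternatives
        and all(alt - {host_cultivar} for alt in presence.ambiguous_alternatives)
    ):
        cross_detected = True
        cross_set = presence.ambiguous_alternatives[0] - {host_cultivar}

    if cross_detected and self_detected:
        return ClassificationResult(Category.MIXED, 1, frozenset(cross_set))
    if cross_detected:
        return ClassificationResult(Category.CROSS_ONLY, 1, frozenset(cross_set))
    if self_detected:
        return ClassificationResult(Category.SELF_ONLY, 0, frozenset())
    return ClassificationResult(Category.UNDETERMINED, None, frozenset())


def calls_from_frame(calls: pd.DataFrame) -> dict[str, AlleleCallSet]:
    """Build per-bee call sets from a long-format calls table.

    Expected columns: ``bee_id``, ``locus_id``, ``assay`` in {ALT, REF},
    ``detected`` in {0, 1}.
    """
    required = {"bee_id", "locus_id", "assay", "detected"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns: {sorted(missing)}")
    out: dict[str, AlleleCallSet] = {}
    for bee_id, sub in calls.groupby("bee_id", sort=False):
        per_locus: dict[str, tuple[bool, bool | None]] = {}
        for locus_id, lsub in sub.groupby("locus_id", sort=False):
            alt = ref = None
            for _, row in lsub.iterrows():
                if row["assay"] == "ALT":
                    alt = bool(int(row["detected"]))
                elif row["assay"] == "REF":
                    ref = bool(int(row["detected"]))
                else:
                    raise ValueError(f"unknown assay {row['assay']!r}")
            per_locus[str(locus_id)] = (bool(alt), ref)
        out[str(bee_id)] = AlleleCallSet(bee_id=str(bee_id), calls=per_locus)
    return out


def deconvolve_dataset(
    calls: pd.DataFrame,
    panel: PanelDesign,
    metadata: pd.DataFrame,
    ambiguity_policy: str = "any_cover_cross",
) -> pd.DataFrame:
    """Deconvolve and classify every bee in a study.

    ``metadata`` must carry ``bee_id`` and ``host_cultivar`` (transect and
    distance columns are passed through when present).  Returns one row per
    bee with the inferred cultivar set, category and score; UNDETERMINED
    bees carry ``included = False`` for downstream exclusion.
    """
    if calls.empty:
        return pd.DataFrame(
            columns=["bee_id", "host_cultivar", "category", "score", "included",
                     "confirmed", "cross_cultivars", "ambiguous", "n_alt_detections"]
        )
    call_sets = calls_from_frame(calls)
    meta = metadata.set_index(metadata["bee_id"].astype(str))
    rows = []
    passthrough = [c for c in ("transect_id", "orchard_type", "row_index",
                               "distance_m") if c in metadata.columns]
    for bee_id, cs in call_sets.items():
        if bee_id not in meta.index:
            raise KeyError(f"bee {bee_id!r} has calls but no metadata/host")
        host = meta.at[bee_id, "host_cultivar"]
        presence = interpret_calls(cs, panel)
        result = classify_bee(presence, host, panel, ambiguity_policy)
        row = {
            "bee_id": bee_id,
            "host_cultivar": host,
            "category": result.category.value,
            "score": result.score,
            "included": result.category is not Category.UNDETERMINED,
            "confirmed": ";".join(sorted(presence.confirmed)),
            "cross_cultivars": ";".join(sorted(result.cross_cultivars)),
            "ambiguous": bool(presence.ambiguous_alternatives),
            "n_alt_detections": len(presence.detected_loci),
        }
        for col in passthrough:
            row[col] = meta.at[bee_id, col]
        rows.append(row)
    return pd.DataFrame(rows)
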