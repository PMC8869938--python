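"""Rule engines for early-stage (FIGO I–II) endometrial-cancer risk groups.

Four pure decision functions over categorical clinicopathological and
molecular inputs:

* :func:`classify_2016` — the ESMO-ESGO-ESTRO 2016 clinicopathological
  four-group scheme (low / intermediate / high-intermediate / high);
* :func:`assign_molecular_subtype` — the ProMisE surrogate of the TCGA
  molecular classes (POLE / MMRd / NSMP / p53abn), with POLE restricted to
  a configurable whitelist of pathogenic exonuclease-domain variants;
* :func:`classify_2020` — the ESGO-ESTRO-ESP 2020 molecular-integrated
  four-group scheme;
* :func:`classify_proposal` — a three-tier refinement of the 2020 scheme
  that reallocates CTNNB1 exon-3 mutated intermediate patients to the
  high-risk group and merges the remaining intermediates.

Every engine is total over its input vocabulary: each combination yields
exactly one label or one *explicit* unclassifiable outcome (a string
starting with ``"unclassifiable"``), never a silent default.  Callers are
expected to resolve NE (non-evaluable) inputs through the imputation
module before classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .cohort import NE, Cohort, PatientRecord

__all__ = [
    "MOLECULAR_SUBTYPES",
    "RISK_GROUPS_4",
    "RISK_GROUPS_3",
    "PoleWhitelist",
    "is_pole_pathogenic",
    "assign_molecular_subtype",
    "classify_2016",
    "classify_2020",
    "classify_proposal",
    "classify_cohort",
    "is_unclassifiable",
]

MOLECULAR_SUBTYPES = ["POLE", "MMRd", "NSMP", "p53abn"]
RISK_GROUPS_4 = ["low", "intermediate", "high_intermediate", "high"]
RISK_GROUPS_3 = ["low", "intermediate", "high"]

UNCLASSIFIABLE_LVSI = "unclassifiable: missing LVSI"
UNCLASSIFIABLE_MOLECULAR = "unclassifiable: missing molecular data"


def is_unclassifiable(label: str) -> bool:
    return label.startswith("unclassifiable")


@dataclass(frozen=True)
class PoleWhitelist:
    """Pathogenic POLE exonuclease-domain variants accepted for classification.

    The default list is the 11 hotspot amino-acid changes in exons 9/13/14
    commonly accepted as pathogenic; any other exonuclease-domain alteration
    is ignored for subtyping.  Membership is case-insensitive on the stripped
    token.  The list ships as JSON package data so it can be revised without
    code changes.
    """

    variants: frozenset[str] = field(default_factory=lambda: _default_whitelist())

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("POLE whitelist must be non-empty")
        object.__setattr__(
            self, "variants", frozenset(v.strip().upper() for v in self.variants)
        )

    def __contains__(self, variant: str) -> bool:
        return variant.strip().upper() in self.variants

    @classmethod
    def from_json(cls, path) -> "PoleWhitelist":
        with open(path) as fh:
            return cls(frozenset(json.load(fh)))


def _default_whitelist() -> frozenset[str]:
    text = resources.files("endorisk.data").joinpath("pole_whitelist.json").read_text()
    return frozenset(json.loads(text))


def is_pole_pathogenic(variant: str, whitelist: PoleWhitelist | None = None) -> bool:
    """True iff ``variant`` is a whitelisted pathogenic change ("" → False)."""
    if not variant or not variant.strip():
        return False
    return variant in (whitelist or PoleWhitelist())


def assign_molecular_subtype(
    record: PatientRecord, whitelist: PoleWhitelist | None = None
) -> str:
    """ProMisE surrogate subtype with precedence POLE → MMRd → p53abn → NSMP.

    A pathogenic POLE variant dominates every other call; MMR deficiency
    dominates aberrant p53; NSMP is the residual class.  NE marker values
    that the cascade still needs produce an explicit unclassifiable outcome.
    """
    if is_pole_pathogenic(record.pole_variant, whitelist):
        return "POLE"
    if record.mmr_status == "deficient":
        return "MMRd"
    if record.mmr_status == NE:
        return UNCLASSIFIABLE_MOLECULAR
    if record.p53_ihc == "abnormal":
        return "p53abn"
    if record.p53_ihc == NE:
        return UNCLASSIFIABLE_MOLECULAR
    return "NSMP"


def classify_2016(record: PatientRecord) -> str:
    """ESMO-ESGO-ESTRO 2016 risk group from clinicopathological features.

    Rule table (stage I–II domain):

    * **low** — stage IA endometrioid, grade 1–2, LVSI negative;
    * **intermediate** — stage IB endometrioid, grade 1–2, LVSI negative;
    * **high-intermediate** — stage IA endometrioid grade 3 (any LVSI), or
      stage I endometrioid grade 1–2 with positive LVSI (any depth);
    * **high** — stage IB endometrioid grade 3, stage II, or any
      non-endometrioid histology.
    """
    if record.histology == "NEEC" or record.figo_stage == "II":
        return "high"
    # endometrioid, stage I
    if not record.low_grade:  # G3
        return "high" if record.figo_stage == "IB" else "high_intermediate"
    # endometrioid, stage I, G1–G2: LVSI decides
    if record.lvsi == NE:
        return UNCLASSIFIABLE_LVSI
    if record.lvsi == "positive":
        return "high_intermediate"
    return "low" if record.figo_stage == "IA" else "intermediate"


def classify_2020(record: PatientRecord, subtype: str) -> str:
    """ESGO-ESTRO-ESP 2020 risk group from clinicopathological features plus
    the molecular subtype.

    Rule table (stage I–II domain):

    * POLE → **low** regardless of stage/histology;
    * p53abn with myometrial invasion → **high**; p53abn without invasion,
      and non-endometrioid MMRd/NSMP without invasion → **intermediate**;
    * non-endometrioid MMRd/NSMP with invasion → **high**;
    * MMRd/NSMP endometrioid: stage IA grade 1–2 LVSI− → **low**; stage IB
      grade 1–2 LVSI− or stage IA grade 3 LVSI− → **intermediate**; stage I
      with positive LVSI (any grade/depth), stage IB grade 3, or stage II →
      **high-intermediate**.

    The cohort's binary LVSI variable maps to the guideline's
    substantial-LVSI branch.
    """
    if is_unclassifiable(subtype):
        return subtype
    if subtype == "POLE":
        return "low"
    invaded = record.myometrial_invasion != "none"
    if subtype == "p53abn":
        return "high" if invaded else "intermediate"
    # MMRd / NSMP
    if record.histology == "NEEC":
        return "high" if invaded else "intermediate"
    # MMRd/NSMP endometrioid
    if record.figo_stage == "II":
        return "high_intermediate"
    if record.figo_stage == "IB" and not record.low_grade:
        return "high_intermediate"
    if record.lvsi == NE:
        return UNCLASSIFIABLE_LVSI
    if record.lvsi == "positive":
        return "high_intermediate"
    if record.figo_stage == "IA":
        return "low" if record.low_grade else "intermediate"
    return "intermediate"  # IB, G1–G2, LVSI−


def classify_proposal(group2020: str, ctnnb1: str) -> str:
    """Three-tier CTNNB1-augmented refinement of the 2020 scheme.

    Low and high 2020 groups pass through unchanged; the two 2020
    intermediate groups merge, with CTNNB1 exon-3 mutated patients
    reallocated to the high-risk group.  A residual NE status (imputation
    declined or failed) is treated as wildtype — the conservative default
    given the low mutation prevalence.
    """
    if is_unclassifiable(group2020):
        return group2020
    if group2020 in ("low", "high"):
        return group2020
    if group2020 not in ("intermediate", "high_intermediate"):
        raise ValueError(f"unknown 2020 risk group: {group2020!r}")
    return "high" if ctnnb1 == "mutated" else "intermediate"


SCHEMES = ("c2016", "promise", "c2020", "proposal")


def classify_record(
    record: PatientRecord, scheme: str, whitelist: PoleWhitelist | None = None
) -> str:
    if scheme == "c2016":
        return classify_2016(record)
    if scheme == "promise":
        return assign_molecular_subtype(record, whitelist)
    subtype = assign_molecular_subtype(record, whitelist)
    g2020 = classify_2020(record, subtype)
    if scheme == "c2020":
        return g2020
    if scheme == "proposal":
        return classify_proposal(g2020, record.ctnnb1_exon3)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def classify_cohort(
    cohort: Cohort, scheme: str, whitelist: PoleWhitelist | None = None
) -> pd.Series:
    """Label every patient under ``scheme``.

    Returns a Series indexed like the cohort, named ``"<scheme>_group"``.
    Unclassifiable outcomes appear verbatim in the table; they are never
    dropped silently.
    """
    labels = [classify_record(rec, scheme, whitelist) for rec in cohort]
    return pd.Series(labels, index=cohort.df.index, name=f"{scheme}_group")
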