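"""Compound ingestion, standardization, filtering and inhibition labelling.

The five drug-metabolizing cytochrome P450 isoforms considered throughout the
package are CYP1A2, CYP2C9, CYP2C19, CYP2D6 and CYP3A4.  A compound is called
an *inhibitor* of an isoform when its AC50 is at most 10 uM (or its PubChem
activity score exceeds 40), a *non-inhibitor* when AC50 exceeds 57 uM (or the
activity score is exactly 0), and *indeterminate* in between.  Compounds with
a definite call for all five isoforms get an inhibited-isoform count 0-5 and
fall into one of three categories: non-inhibitor (0), non-extensive inhibitor
(1-2) or multi-P450 inhibitor (3-5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ISOFORMS = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4")

AC50_INHIBITOR_MAX_UM = 10.0
AC50_NON_INHIBITOR_MIN_UM = 57.0
SCORE_INHIBITOR_MIN = 40.0
MW_LIMIT_DA = 800.0

#: counter-ions stripped during salt standardization (canonical SMILES).
DEFAULT_COUNTER_IONS = frozenset(
    {
        "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[NH4+]",
        "[Cl-]", "[Br-]", "[I-]", "[F-]", "[OH-]", "O=S(=O)([O-])[O-]",
        "O=S(=O)([O-])O", "[O-][N+](=O)[O-]", "O=C([O-])[O-]", "[H+]",
    }
)


class InhibitionCall(str, Enum):
    """Per-isoform inhibition call."""

    INHIBITOR = "inhibitor"
    NON_INHIBITOR = "non_inhibitor"
    INDETERMINATE = "indeterminate"
    MISSING = "missing"


class Category(str, Enum):
    """Compound category by number of inhibited isoforms."""

    NON_INHIBITOR = "non_inhibitor"
    NON_EXTENSIVE = "non_extensive_inhibitor"
    MULTI_P450 = "multi_p450_inhibitor"
    INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class IsoformEvidence:
    """One piece of inhibition evidence for one isoform.

    ``measure_kind`` is one of ``ac50_uM`` (concentration in micromolar),
    ``pubchem_activity_score`` (unitless, 0-100) or ``direct_call`` (a
    pre-made :class:`InhibitionCall` token, e.g. from curated tables that
    ship calls rather than raw assay values).
    """

    isoform: str
    measure_kind: str
    value: float | str

    def __post_init__(self) -> None:
        if self.isoform not in ISOFORMS:
            raise ValueError(f"unknown isoform {self.isoform!r}; expected one of {ISOFORMS}")
        if self.measure_kind not in ("ac50_uM", "pubchem_activity_score", "direct_call"):
            raise ValueError(f"unknown measure_kind {self.measure_kind!r}")
        if self.measure_kind == "ac50_uM":
            v = float(self.value)
            if not v > 0 or math.isnan(v):
                raise ValueError("AC50 must be a positive concentration in uM")
        elif self.measure_kind == "pubchem_activity_score":
            v = float(self.value)
            if v < 0 or math.isnan(v):
                raise ValueError("activity score must be nonnegative")


@dataclass
class CompoundRecord:
    """A single chemical with its per-isoform calls and derived labels."""

    id: str
    smiles: str
    mol_weight: float | None = None
    calls: dict[str, InhibitionCall] = field(default_factory=dict)

    @property
    def inhibited_count(self) -> int | None:
        try:
            return count_inhibited(self.calls)
        except KeyError:
            return None

    @property
    def category(self) -> Category:
        n = self.inhibited_count
        return Category.INCOMPLETE if n is None else categorize(n)


@dataclass
class CurationReport:
    """Accounting of a curation pass; kept + excluded always equals input."""

    kept: int = 0
    excluded_by_mw: int = 0
    excluded_inorganic: int = 0
    excluded_mixture: int = 0
    excluded_unparsable: int = 0
    standardized: int = 0
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return (
            self.excluded_by_mw
            + self.excluded_inorganic
            + self.excluded_mixture
            + self.excluded_unparsable
        )

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "excluded_by_mw": self.excluded_by_mw,
            "excluded_inorganic": self.excluded_inorganic,
            "excluded_mixture": self.excluded_mixture,
            "excluded_unparsable": self.excluded_unparsable,
            "standardized": self.standardized,
            "reasons": dict(self.reasons),
        }


class StandardizationError(ValueError):
    """Structure rejected during standardization; ``.reason`` says why."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


def classify_call(evidence: IsoformEvidence) -> InhibitionCall:
    """Turn one piece of assay evidence into an inhibition call.

    AC50 <= 10 uM -> inhibitor, AC50 > 57 uM -> non-inhibitor, in between ->
    indeterminate (the 57 uM boundary itself is indeterminate: the
    non-inhibitor rule is strictly greater-than).  Activity score > 40 ->
    inhibitor, score == 0 -> non-inhibitor, 0 < score <= 40 -> indeterminate.
    Direct calls pass through.
    """
    if evidence.measure_kind == "direct_call":
        return InhibitionCall(evidence.value)
    v = float(evidence.value)
    if evidence.measure_kind == "ac50_uM":
        if v <= AC50_INHIBITOR_MAX_UM:
            return InhibitionCall.INHIBITOR
        if v > AC50_NON_INHIBITOR_MIN_UM:
            return InhibitionCall.NON_INHIBITOR
        return InhibitionCall.INDETERMINATE
    # pubchem_activity_score
    if v > SCORE_INHIBITOR_MIN:
        return InhibitionCall.INHIBITOR
    if v == 0:
        return InhibitionCall.NON_INHIBITOR
    return InhibitionCall.INDETERMINATE


def count_inhibited(calls: Mapping[str, InhibitionCall]) -> int | None:
    """Number of inhibited isoforms, or None when any call is not definite.

    Requires all five isoform keys to be present; raises KeyError otherwise.
    """
    missing = [iso for iso in ISOFORMS if iso not in calls]
    if missing:
        raise KeyError(f"missing isoform calls: {missing}")
    vals = [InhibitionCall(calls[iso]) for iso in ISOFORMS]
    if any(c in (InhibitionCall.INDETERMINATE, InhibitionCall.MISSING) for c in vals):
        return None
    return sum(c is InhibitionCall.INHIBITOR for c in vals)


def categorize(count: int) -> Category:
    """Map an inhibited-isoform count to its category (0 / 1-2 / 3-5)."""
    if not 0 <= count <= 5:
        raise ValueError(f"count must be in 0..5, got {count}")
    if count == 0:
        return Category.NON_INHIBITOR
    if count <= 2:
        return Category.NON_EXTENSIVE
    return Category.MULTI_P450


def _is_water(frag: Chem.Mol) -> bool:
    return Chem.MolToSmiles(frag) in ("O", "[OH2]")


def standardize_structure(
    smiles: str,
    counter_ions: frozenset[str] = DEFAULT_COUNTER_IONS,
) -> str:
    """Standardize a SMILES: drop waters, strip salt counter-ions, neutralize.

    Returns the canonical SMILES of the single remaining organic fragment.
    Raises :class:`StandardizationError` with reason ``inorganic`` (no carbon
    left), ``mixture`` (more than one fragment survives stripping) or
    ``unparsable``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError("unparsable", f"cannot parse SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    frags = [f for f in frags if not _is_water(f)]
    if not frags:
        raise StandardizationError("inorganic", "nothing but water")
    kept = [f for f in frags if Chem.MolToSmiles(f) not in counter_ions]
    if not kept:
        raise StandardizationError("inorganic", "only counter-ions present")
    if len(kept) > 1:
        raise StandardizationError("mixture", f"{len(kept)} fragments after salt/water stripping")
    frag = kept[0]
    if not any(a.GetAtomicNum() == 6 for a in frag.GetAtoms()):
        raise StandardizationError("inorganic", "carbon-free structure")
    frag = rdMolStandardize.Uncharger().uncharge(frag)
    Chem.SanitizeMol(frag)
    return Chem.MolToSmiles(frag)


def molecular_weight(smiles: str) -> float:
    """Average molecular weight (Da) of a SMILES structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError("unparsable", f"cannot parse SMILES {smiles!r}")
    return Descriptors.MolWt(mol)


def filter_by_weight(
    records: Sequence[CompoundRecord],
    limit: float = MW_LIMIT_DA,
    report: CurationReport | None = None,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Keep records with molecular weight strictly below ``limit`` Daltons.

    Weight is computed from the structure when absent.  Records whose weight
    cannot be determined are excluded with reason ``unparsable``.
    """
    rep = report if report is not None else CurationReport()
    kept: list[CompoundRecord] = []
    for rec in records:
        mw = rec.mol_weight
        if mw is None:
            try:
                mw = molecular_weight(rec.smiles)
                rec.mol_weight = mw
            except StandardizationError:
                rep.excluded_unparsable += 1
                rep.reasons[rec.id] = "unparsable"
                continue
        if mw < limit:
            kept.append(rec)
        else:
            rep.excluded_by_mw += 1
            rep.reasons[rec.id] = "mw"
    rep.kept = len(kept)
    return kept, rep


def curate(
    records: Iterable[CompoundRecord],
    mw_limit: float = MW_LIMIT_DA,
    counter_ions: frozenset[str] = DEFAULT_COUNTER_IONS,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Full curation pass: standardize structures then apply the weight filter."""
    rep = CurationReport()
    survivors: list[CompoundRecord] = []
    for rec in records:
        try:
            std = standardize_structure(rec.smiles, counter_ions)
        except StandardizationError as err:
            key = "excluded_" + (err.reason if err.reason != "unparsable" else "unparsable")
            setattr(rep, key, getattr(rep, key) + 1)
            rep.reasons[rec.id] = err.reason
            continue
        if std != rec.smiles:
            rep.standardized += 1
        rec.smiles = std
        rec.mol_weight = None  # recompute from the standardized structure
        survivors.append(rec)
    kept, rep = filter_by_weight(survivors, mw_limit, rep)
    return kept, rep


def records_from_table(
    table: pd.DataFrame,
    dedup: str = "keep_first",
) -> list[CompoundRecord]:
    """Build records from a table with ``id``, ``smiles`` and evidence columns.

    Evidence columns are ``<isoform>_ac50`` / ``<isoform>_score`` /
    ``<isoform>_call`` (lowercase isoform names).  ``dedup`` handles repeated
    ids: ``keep_first`` keeps the first row, ``strictest_call`` keeps, per
    isoform, the inhibitor call over non-inhibitor over indeterminate.
    """
    if dedup not in ("keep_first", "strictest_call"):
        raise ValueError(f"unknown dedup policy {dedup!r}")
    strictness = {
        InhibitionCall.INHIBITOR: 0,
        InhibitionCall.NON_INHIBITOR: 1,
        InhibitionCall.INDETERMINATE: 2,
        InhibitionCall.MISSING: 3,
    }
    out: dict[str, CompoundRecord] = {}
    for _, row in table.iterrows():
        calls: dict[str, InhibitionCall] = {}
        for iso in ISOFORMS:
            low = iso.lower()
            call = InhibitionCall.MISSING
            if f"{low}_ac50" in row.index and pd.notna(row[f"{low}_ac50"]):
                call = classify_call(IsoformEvidence(iso, "ac50_uM", float(row[f"{low}_ac50"])))
            elif f"{low}_score" in row.index and pd.notna(row[f"{low}_score"]):
                call = classify_call(
                    IsoformEvidence(iso, "pubchem_activity_score", float(row[f"{low}_score"]))
                )
            elif f"{low}_call" in row.index and pd.notna(row[f"{low}_call"]):
                call = InhibitionCall(row[f"{low}_call"])
            calls[iso] = call
        rid = str(row["id"])
        rec = CompoundRecord(id=rid, smiles=str(row["smiles"]), calls=calls)
        if rid not in out:
            out[rid] = rec
        elif dedup == "strictest_call":
            prev = out[rid]
            for iso in ISOFORMS:
                if strictness[rec.calls[iso]] < strictness[prev.calls[iso]]:
                    prev.calls[iso] = rec.calls[iso]
    return list(out.values())
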