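"""Active-site signature extraction and residue-rule family classification.

The five functional families of the LarA superfamily can be told apart, to a
useful approximation, by the residues a sequence carries at the positions
equivalent to F175, F176, W358 and T359 of LarA1 (substrate-selectivity
positions flanking the nickel-pincer cofactor site):

=======  =====  =====  =====  =====
family    175    176    358    359
=======  =====  =====  =====  =====
LAR        F      F      W     E/Q
GntE       E      V      A      H
HGR        Y      F     H/Q     T
MAR        –      –     H/Q     K
HHR        –      –     F/Y     –
=======  =====  =====  =====  =====

("–" = unconstrained.)  Classification evaluates rules most-constrained
first: a fully matched 4-position rule beats a fully matched 2-position rule,
and two fully matched rules of equal constraint count yield ``ambiguous``.
The rules are "usually" rules, not theorems — characterized lactate racemases
with T or C at the 359-equivalent position fall outside the strict LAR set,
which is why an ``extended`` rule table (LAR 359 set widened to {E,Q,T,C}) is
provided but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import AlignmentParams, global_align, map_reference_positions
from .repertoire import ProteinRecord

__all__ = [
    "SignatureProfile",
    "FamilyRule",
    "FamilyCall",
    "DEFAULT_RULES",
    "EXTENDED_RULES",
    "extract_signature",
    "classify",
    "annotate_batch",
    "SignatureFamilyClassifier",
    "load_rules",
]

_SIGNATURE_POSITIONS = (175, 176, 358, 359)
_CATALYTIC_POSITIONS = (108, 174)
_BINDING_POSITIONS = (75, 184, 200)


@dataclass(frozen=True)
class SignatureProfile:
    """Residues found at the LarA1-equivalent diagnostic and active-site
    positions of a query (None where the position maps to a query gap)."""

    res175: str | None
    res176: str | None
    res358: str | None
    res359: str | None
    catalytic_his_108: str | None = None
    catalytic_his_174: str | None = None
    binding_75: str | None = None
    binding_184: str | None = None
    binding_200: str | None = None

    def diagnostic(self) -> dict[int, str | None]:
        return {
            175: self.res175,
            176: self.res176,
            358: self.res358,
            359: self.res359,
        }


@dataclass(frozen=True)
class FamilyRule:
    """Allowed residue sets at a subset of the diagnostic positions."""

    family: str
    allowed: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        for pos, residues in self.allowed:
            if pos not in _SIGNATURE_POSITIONS:
                raise ValueError(f"rule position {pos} not a diagnostic position")
            if not residues:
                raise ValueError(f"empty residue set at position {pos}")

    @property
    def n_constrained(self) -> int:
        return len(self.allowed)

    def matches(self, profile: SignatureProfile) -> bool:
        diag = profile.diagnostic()
        return all(
            diag[pos] is not None and diag[pos] in residues
            for pos, residues in self.allowed
        )


def _rule(family: str, spec: dict[int, str]) -> FamilyRule:
    return FamilyRule(
        family=family,
        allowed=tuple((pos, frozenset(res)) for pos, res in sorted(spec.items())),
    )


DEFAULT_RULES: tuple[FamilyRule, ...] = (
    _rule("LAR", {175: "F", 176: "F", 358: "W", 359: "EQ"}),
    _rule("GntE", {175: "E", 176: "V", 358: "A", 359: "H"}),
    _rule("HGR", {175: "Y", 176: "F", 358: "HQ", 359: "T"}),
    _rule("MAR", {358: "HQ", 359: "K"}),
    _rule("HHR", {358: "FY"}),
)

# Widened LAR rule admitting the T/C carried by characterized lactate
# racemases that the strict "usually" set misses.
EXTENDED_RULES: tuple[FamilyRule, ...] = (
    _rule("LAR", {175: "F", 176: "F", 358: "W", 359: "EQTC"}),
) + DEFAULT_RULES[1:]


@dataclass(frozen=True)
class FamilyCall:
    """Outcome of residue-rule classification for one profile."""

    family: str  # a family name, "unclassified", or "ambiguous"
    matched_rule: FamilyRule | None = None
    alternatives: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def extract_signature(
    query: ProteinRecord,
    reference: ProteinRecord | None = None,
    params: AlignmentParams | None = None,
) -> SignatureProfile:
    """Read the query residues equivalent to the LarA1 diagnostic and
    active-site positions, via global alignment against the reference.

    Defaults to the packaged LarA1-numbered reference scaffold.  Positions
    whose reference residue aligns to a query gap come back as None.
    """
    if reference is None:
        from .simulate import reference_record

        reference = reference_record()
    result = global_align(query.sequence, reference.sequence, params)
    positions = sorted(
        set(_SIGNATURE_POSITIONS) | set(_CATALYTIC_POSITIONS) | set(_BINDING_POSITIONS)
    )
    pmap = map_reference_positions(result, positions)

    def residue(pos: int) -> str | None:
        qpos = pmap.get(pos)
        return query.sequence[qpos - 1] if qpos is not None else None

    return SignatureProfile(
        res175=residue(175),
        res176=residue(176),
        res358=residue(358),
        res359=residue(359),
        catalytic_his_108=residue(108),
        catalytic_his_174=residue(174),
        binding_75=residue(75),
        binding_184=residue(184),
        binding_200=residue(200),
    )


def classify(
    profile: SignatureProfile, rules: Sequence[FamilyRule] = DEFAULT_RULES
) -> FamilyCall:
    """Assign a family by the most-constrained fully-matched rule.

    The outcome is independent of the order in which rules are supplied:
    matching rules are ranked by constraint count, two fully matched rules
    of equal (maximal) count give ``ambiguous``, no match gives
    ``unclassified``.  Missing diagnostic positions and absent catalytic-His
    equivalents are flagged but do not veto classification.
    """
    if not rules:
        raise ValueError("empty rule list")
    flags: list[str] = []
    diag = profile.diagnostic()
    missing = [str(pos) for pos, res in sorted(diag.items()) if res is None]
    if missing:
        flags.append("unmapped_position:" + ",".join(missing))
    if profile.catalytic_his_108 != "H" and profile.catalytic_his_174 != "H":
        flags.append("no_catalytic_his")

    matched = sorted(
        (r for r in rules if r.matches(profile)),
        key=lambda r: (-r.n_constrained, r.family),
    )
    if not matched:
        return FamilyCall(family="unclassified", flags=tuple(flags))
    top_n = matched[0].n_constrained
    top = [r for r in matched if r.n_constrained == top_n]
    others = tuple(r.family for r in matched if r is not matched[0])
    if len(top) > 1:
        return FamilyCall(
            family="ambiguous",
            alternatives=tuple(r.family for r in top),
            flags=tuple(flags),
        )
    return FamilyCall(
        family=matched[0].family,
        matched_rule=matched[0],
        alternatives=others,
        flags=tuple(flags),
    )


class SignatureFamilyClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based family classifier over protein records.

    A fixed-rule classifier: ``fit`` only freezes the rule table and the
    reference scaffold (there is nothing to estimate), after which
    ``predict`` maps records to family names through alignment-based
    signature extraction.
    """

    def __init__(
        self,
        rules: Sequence[FamilyRule] | None = None,
        reference: ProteinRecord | None = None,
        alignment_params: AlignmentParams | None = None,
    ):
        self.rules = rules
        self.reference = reference
        self.alignment_params = alignment_params

    def fit(self, X=None, y=None):
        rules = tuple(self.rules) if self.rules is not None else DEFAULT_RULES
        if not rules:
            raise ValueError("empty rule list")
        self.rules_ = rules
        if self.reference is not None:
            self.reference_ = self.reference
        else:
            from .simulate import reference_record

            self.reference_ = reference_record()
        self.classes_ = np.array(
            sorted({r.family for r in rules} | {"unclassified", "ambiguous"})
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "rules_"):
            self.fit()

    def predict_calls(self, X: Sequence[ProteinRecord]) -> list[FamilyCall]:
        self._check_fitted()
        calls = []
        for rec in X:
            try:
                profile = extract_signature(rec, self.reference_, self.alignment_params)
                calls.append(classify(profile, self.rules_))
            except ValueError as exc:
                calls.append(
                    FamilyCall(family="unclassified", flags=(f"error:{exc}",))
                )
        return calls

    def predict(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        return np.array([c.family for c in self.predict_calls(X)])


def annotate_batch(
    records: Sequence[ProteinRecord],
    reference: ProteinRecord | None = None,
    rules: Sequence[FamilyRule] = DEFAULT_RULES,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Classify a batch of records; one row per record, input order kept.

    Per-record failures become flagged ``unclassified`` rows rather than
    aborting the batch.
    """
    if not records:
        raise ValueError("empty record batch")
    clf = SignatureFamilyClassifier(
        rules=rules, reference=reference, alignment_params=params
    ).fit()
    rows = []
    for rec in records:
        try:
            profile = extract_signature(rec, clf.reference_, params)
        except ValueError as exc:
            rows.append(
                {
                    "id": rec.id,
                    "res175": None,
                    "res176": None,
                    "res358": None,
                    "res359": None,
                    "family": "unclassified",
                    "flags": f"error:{exc}",
                }
            )
            continue
        call = classify(profile, clf.rules_)
        rows.append(
            {
                "id": rec.id,
                "res175": profile.res175,
                "res176": profile.res176,
                "res358": profile.res358,
                "res359": profile.res359,
                "family": call.family,
                "flags": ";".join(call.flags),
            }
        )
    return pd.DataFrame(rows)


def load_rules(path: str | Path) -> tuple[FamilyRule, ...]:
    """Read a plain-text rule table: ``family  position  residues`` per line
    (``#`` comments allowed), e.g. ``LAR 359 EQ``."""
    per_family: dict[str, dict[int, str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            family, pos, residues = line.split()
            per_family.setdefault(family, {})[int(pos)] = residues
        except ValueError as exc:
            raise ValueError(f"bad rule line {raw!r}") from exc
    if not per_family:
        raise ValueError(f"no rules found in {path}")
    return tuple(_rule(f, spec) for f, spec in per_family.items())
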