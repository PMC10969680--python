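"""Claim and protocol conformance checking.

Two rule engines:

* ``check_claims`` compares computed performance metrics against the
  QIBA claim thresholds (shipped in ``data/qiba_claims.yaml``).
* ``check_protocol_compliance`` grades acquisition metadata against a
  protocol specification — the single-tier phantom protocol or the
  tiered (ideal / target / acceptable) clinical brain protocol.

Both ship as versioned YAML data files rather than code, since profile
revisions change thresholds, not logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .metrics import MetricResult
from .phantom import AcquisitionParams

__all__ = [
    "ClaimSpec", "TierRule", "ProtocolSpec", "ParameterVerdict",
    "ConformanceReport", "load_claims", "load_protocol",
    "check_claims", "check_protocol_compliance",
]

_TIERS = ("ideal", "target", "acceptable")
_COMPARATORS = ("abs_le", "le", "lt", "ge", "gt", "range", "ci_within")


class SpecConfigError(ValueError):
    """Malformed claim or protocol specification."""


@dataclass(frozen=True)
class ClaimSpec:
    metric: str
    cmp: str
    threshold: float | None = None
    lo: float | None = None
    hi: float | None = None
    units: str = ""
    applicability: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.cmp not in _COMPARATORS:
            raise SpecConfigError(f"claim {self.metric!r}: unknown "
                                  f"comparator {self.cmp!r}")
        if self.cmp in ("range", "ci_within"):
            if self.lo is None or self.hi is None or self.lo >= self.hi:
                raise SpecConfigError(
                    f"claim {self.metric!r}: range needs lo < hi")
        elif self.threshold is None:
            raise SpecConfigError(f"claim {self.metric!r}: missing threshold")

    def evaluate(self, value) -> bool | None:
        """True/False verdict, or None when the metric is not evaluable."""
        if value is None:
            return None
        if self.cmp == "ci_within":
            lo, hi = value  # value is the (lo, hi) confidence interval
            return bool(self.lo <= lo and hi <= self.hi)
        v = float(value)
        if self.cmp == "abs_le":
            return bool(abs(v) <= self.threshold)
        if self.cmp == "le":
            return bool(v <= self.threshold)
        if self.cmp == "lt":
            return bool(v < self.threshold)
        if self.cmp == "ge":
            return bool(v >= self.threshold)
        if self.cmp == "gt":
            return bool(v > self.threshold)
        return bool(self.lo <= v <= self.hi)  # range

    def text(self) -> str:
        if self.cmp == "ci_within":
            return f"95% CI within [{self.lo}, {self.hi}]"
        if self.cmp == "range":
            return f"in [{self.lo}, {self.hi}] {self.units}".strip()
        sym = {"abs_le": "|x| <=", "le": "<=", "lt": "<",
               "ge": ">=", "gt": ">"}[self.cmp]
        return f"{sym} {self.threshold} {self.units}".strip()


@dataclass(frozen=True)
class TierRule:
    """Predicate over one acquisition parameter value."""

    equals: object = None
    one_of: tuple = ()
    min: float | None = None
    max: float | None = None
    min_exclusive: float | None = None
    max_exclusive: float | None = None

    def satisfied(self, value) -> bool:
        if self.equals is not None:
            return _values_equal(value, self.equals)
        if self.one_of:
            return any(_values_equal(value, opt) for opt in self.one_of)
        v = float(value)
        if self.min is not None and v < self.min:
            return False
        if self.max is not None and v > self.max:
            return False
        if self.min_exclusive is not None and v <= self.min_exclusive:
            return False
        if self.max_exclusive is not None and v >= self.max_exclusive:
            return False
        return True


def _values_equal(a, b) -> bool:
    if isinstance(a, (list, tuple)) or isinstance(b, (list, tuple)):
        a = list(a) if isinstance(a, (list, tuple)) else [a]
        b = list(b) if isinstance(b, (list, tuple)) else [b]
        return len(a) == len(b) and all(
            float(x) == float(y) for x, y in zip(a, b))
    return float(a) == float(b)


@dataclass(frozen=True)
class ProtocolSpec:
    """Tier rules for one parameter (ideal / target / acceptable)."""

    parameter: str
    tiers: dict[str, TierRule]

    def __post_init__(self) -> None:
        if "acceptable" not in self.tiers:
            raise SpecConfigError(
                f"parameter {self.parameter!r}: acceptable tier is required")

    def grade(self, value) -> str:
        """Highest tier satisfied, or 'non_conformant'."""
        for tier in _TIERS:
            rule = self.tiers.get(tier)
            if rule is not None and rule.satisfied(value):
                # monotone-tier consistency of the shipped specs
                for lower in _TIERS[_TIERS.index(tier) + 1:]:
                    low = self.tiers.get(lower)
                    if low is not None and not low.satisfied(value):
                        raise SpecConfigError(
                            f"parameter {self.parameter!r}: value {value!r} "
                            f"satisfies {tier} but not {lower} "
                            f"(tiers not nested)")
                return tier
        return "non_conformant"


@dataclass(frozen=True)
class ParameterVerdict:
    parameter: str
    value: object
    tier: str  # ideal | target | acceptable | non_conformant | unknown | waived
    note: str = ""


@dataclass
class ConformanceReport:
    """Combined claim + protocol verdicts for one exam or scanner."""

    metrics: list[MetricResult] = field(default_factory=list)
    parameters: list[ParameterVerdict] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool | None:
        """True iff no claim failed and no parameter is non-conformant.

        None (not evaluable) when a required parameter is missing from
        the metadata while nothing failed outright.
        """
        if any(m.passed is False for m in self.metrics):
            return False
        if any(p.tier == "non_conformant" for p in self.parameters):
            return False
        if any(p.tier == "unknown" for p in self.parameters):
            return None
        return True

    def to_dict(self) -> dict:
        return {
            "metrics": [
                {"metric": m.name, "value": m.value, "units": m.units,
                 "claim": m.claim,
                 "passed": {True: "pass", False: "fail",
                            None: "not_evaluable"}[m.passed]}
                for m in self.metrics
            ],
            "parameters": [
                {"parameter": p.parameter, "value": p.value, "tier": p.tier,
                 **({"note": p.note} if p.note else {})}
                for p in self.parameters
            ],
            "overall_pass": self.overall_pass,
        }

    def to_text(self) -> str:
        lines = ["metric                     value        claim              verdict",
                 "-" * 68]
        for m in self.metrics:
            verdict = {True: "pass", False: "FAIL",
                       None: "not evaluable"}[m.passed]
            val = "NA" if m.value is None else (
                f"{m.value:.3f}" if isinstance(m.value, float) else str(m.value))
            lines.append(f"{m.name:<26} {val:<12} {m.claim:<18} {verdict}")
        if self.parameters:
            lines += ["", "parameter                  value        tier",
                      "-" * 55]
            for p in self.parameters:
                lines.append(f"{p.parameter:<26} {str(p.value):<12} {p.tier}")
        lines += ["", f"overall: "
                  f"{ {True: 'PASS', False: 'FAIL', None: 'not evaluable'}[self.overall_pass] }"]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# loading

def _read_yaml(name_or_path) -> dict:
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") and p.exists():
        return yaml.safe_load(p.read_text())
    ref = resources.files("qdwiqc.data") / f"{name_or_path}.yaml"
    return yaml.safe_load(ref.read_text())


def load_claims(source: str = "qiba_claims") -> list[ClaimSpec]:
    """Load claim specs from a bundled profile name or a YAML path."""
    doc = _read_yaml(source)
    return [ClaimSpec(**{k: (tuple(v) if k == "one_of" else v)
                         for k, v in c.items()})
            for c in doc["claims"]]


def load_protocol(source: str) -> list[ProtocolSpec]:
    """Load protocol tier specs; ``qiba_phantom`` and ``clinical_brain``
    are bundled."""
    name = {"qiba_phantom": "protocol_qiba_phantom",
            "clinical_brain": "protocol_clinical_brain"}.get(source, source)
    doc = _read_yaml(name)
    specs = []
    for entry in doc["parameters"]:
        entry = dict(entry)
        pname = entry.pop("parameter")
        tiers = {}
        for tier in _TIERS:
            if tier in entry:
                rule = dict(entry.pop(tier))
                if "one_of" in rule:
                    rule["one_of"] = tuple(rule["one_of"])
                tiers[tier] = TierRule(**rule)
        specs.append(ProtocolSpec(pname, tiers))
    return specs


# ---------------------------------------------------------------------------
# evaluation

def check_claims(metrics: list[MetricResult],
                 claims: list[ClaimSpec] | str = "qiba_claims",
                 ) -> ConformanceReport:
    """Evaluate computed metrics against claim specs.

    Metrics without a matching claim are carried through as not
    evaluable; a metric whose value is None (e.g. b-value dependence
    under a two-b protocol) is not evaluable and never fails the report.
    """
    if isinstance(claims, str):
        claims = load_claims(claims)
    by_name = {c.metric: c for c in claims}
    out = []
    for m in metrics:
        claim = by_name.get(m.name)
        if claim is None:
            out.append(MetricResult(m.name, m.value, m.units, None,
                                    "no claim configured", m.detail))
            continue
        value = m.detail.get("ci") if claim.cmp == "ci_within" else m.value
        out.append(MetricResult(m.name, m.value, m.units,
                                claim.evaluate(value), claim.text(),
                                m.detail))
    return ConformanceReport(metrics=out)


def _parameter_value(params: AcquisitionParams, name: str):
    derived = {
        "n_bvalues": params.n_bvalues,
        "highest_b": max(params.b_values),
        "b_values": list(params.b_values),
        "matrix": list(params.matrix),
        "matrix_freq": params.matrix[0],
    }
    if name in derived:
        return derived[name]
    if hasattr(params, name):
        return getattr(params, name)
    return params.extras.get(name)


def check_protocol_compliance(
    params: AcquisitionParams,
    profile: str = "clinical_brain",
    specs: list[ProtocolSpec] | None = None,
    waivers: dict[str, str] | None = None,
) -> ConformanceReport:
    """Grade acquisition metadata against a protocol specification.

    ``waivers`` maps parameter names to a justification; a waived
    parameter is reported but never fails the exam (e.g. a documented
    NEX deviation on one scanner).
    """
    specs = specs if specs is not None else load_protocol(profile)
    waivers = waivers or {}
    verdicts = []
    for spec in specs:
        value = _parameter_value(params, spec.parameter)
        if value is None:
            verdicts.append(ParameterVerdict(spec.parameter, None, "unknown",
                                             "missing from metadata"))
            continue
        tier = spec.grade(value)
        if tier == "non_conformant" and spec.parameter in waivers:
            verdicts.append(ParameterVerdict(spec.parameter, value, "waived",
                                             waivers[spec.parameter]))
            continue
        verdicts.append(ParameterVerdict(spec.parameter, value, tier))
    return ConformanceReport(parameters=verdicts)
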