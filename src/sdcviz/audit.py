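"""Disclosure audit of plot payloads.

Checks a serialized (or serializable) payload against a disclosure policy
and reports:

* **small-cell** violations — any exposed count strictly between 0 and the
  policy's minimum cell size on a payload built from raw observations (for
  grids of already-anonymized points the same finding is a warning, since the
  counted units are not raw records);
* **coincidence** violations — when the raw data are supplied, any
  anonymized point lying within the policy tolerance of a raw point in every
  coordinate (a raw value leaking through unchanged);
* **support-bound** warnings — anonymized values escaping a declared
  variable support (a known feature of the centroid-rescale and noise
  engines on bounded distributions);
* **100%-cell** warnings — a grid row or column whose displayed occupancy
  sits in a single cell, so that cell characterizes every displayed member
  of its margin;
* **complementary-suppression** warnings — when a payload carries marginal
  totals, a margin with exactly one suppressed cell is flagged: the hidden
  value is recoverable by subtraction.  Choosing the complementary cell is
  left to the data custodian.

``passed`` is true iff there are no violations; warnings never fail an audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError


@dataclass(frozen=True)
class Policy:
    """Disclosure policy: minimum cell size, raw-leak tolerance, optional supports.

    ``support_bounds`` maps variable names ("X", "Y") to (lo, hi) tuples for
    bounded supports such as the unit interval of a beta variable.
    """

    min_cell: int = 3
    coincidence_tol: float = 0.0
    support_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_cell < 1:
            raise ValidationError("min_cell must be >= 1")
        if self.coincidence_tol < 0:
            raise ValidationError("coincidence_tol must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "Policy":
        return cls(
            min_cell=int(d.get("min_cell", 3)),
            coincidence_tol=float(d.get("coincidence_tol", 0.0)),
            support_bounds={k: tuple(v) for k, v in d.get("support_bounds", {}).items()},
        )


@dataclass
class AuditReport:
    """Audit outcome: violations fail the payload, warnings annotate it.

    Each finding is a ``(rule, location, detail)`` triple.
    """

    violations: list
    warnings: list

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "violations": [list(v) for v in self.violations],
            "warnings": [list(w) for w in self.warnings],
        }

    def summary(self) -> str:
        lines = [f"audit: {'PASSED' if self.passed else 'FAILED'}"]
        for rule, loc, detail in self.violations:
            lines.append(f"  violation [{rule}] at {loc}: {detail}")
        for rule, loc, detail in self.warnings:
            lines.append(f"  warning   [{rule}] at {loc}: {detail}")
        return "\n".join(lines)


_RAW_COUNT_METHODS = {"raw", "suppress", "generalize", "kanon"}


def _payload_dict(payload) -> dict:
    if hasattr(payload, "to_dict"):
        payload = payload.to_dict()
    if not isinstance(payload, dict):
        raise SchemaError("payload must be a dict or expose to_dict()")
    for key in ("kind", "method"):
        if key not in payload:
            raise SchemaError(f"payload missing required field {key!r}")
    return payload


def _exposed_counts(d: dict):
    """Yield (location, count) for every count the rendering would expose."""
    kind = d["kind"]
    if kind == "histogram":
        for i, c in enumerate(d["counts"]):
            if c is not None:
                yield f"bin {i}", int(c)
    elif kind in ("heatmap", "contour"):
        for i, row in enumerate(d["counts"]):
            for j, c in enumerate(row):
                if c is not None:
                    yield f"cell ({i}, {j})", int(c)
    elif kind == "sized-dot-scatter":
        for i, (_, _, c) in enumerate(d["dots"]):
            yield f"dot {i}", int(c)
    elif kind == "regression-diagnostics":
        for name in ("resid_vs_fitted", "qq", "resid_vs_leverage"):
            plot = d[name]
            if isinstance(plot, dict) and plot.get("kind") == "sized-dot-scatter":
                for i, (_, _, c) in enumerate(plot["dots"]):
                    yield f"{name} dot {i}", int(c)


def _grid_margin_checks(d: dict, warnings_: list) -> None:
    counts = np.array(
        [[0 if c is None else c for c in row] for row in d["counts"]], dtype=np.int64
    )
    mask = np.asarray(d["mask"], dtype=bool)
    occupied = counts > 0
    suppressed_occupancy = mask  # masked cells had 0 < count < threshold
    visible = occupied & ~mask
    for axis, label in ((1, "row"), (0, "column")):
        vis = visible.sum(axis=axis)
        sup = suppressed_occupancy.sum(axis=axis)
        for idx in np.nonzero(vis == 1)[0]:
            warnings_.append(
                (
                    "100%-cell",
                    f"{label} {idx}",
                    "all displayed occupancy of this margin sits in a single cell",
                )
            )
        if "margins" in d:
            for idx in np.nonzero(sup == 1)[0]:
                warnings_.append(
                    (
                        "complementary-suppression",
                        f"{label} {idx}",
                        "a single suppressed cell is recoverable from this margin's "
                        "total; suppress a complementary cell",
                    )
                )


def _point_arrays(d: dict) -> list:
    """(label, x, y) triples of anonymized point coordinates, if any."""
    out = []
    if d["kind"] == "anon-scatter":
        out.append(("points", np.asarray(d["x"], float), np.asarray(d["y"], float)))
    elif d["kind"] == "regression-diagnostics":
        for name in ("resid_vs_fitted", "qq", "resid_vs_leverage"):
            plot = d[name]
            if isinstance(plot, dict) and "x" in plot and "y" in plot:
                out.append((name, np.asarray(plot["x"], float), np.asarray(plot["y"], float)))
    return out


_KNOWN_KINDS = {
    "histogram",
    "heatmap",
    "contour",
    "sized-dot-scatter",
    "anon-scatter",
    "boxplot",
    "regression-diagnostics",
}


def audit_payload(
    payload, raw: pd.DataFrame | None = None, policy: Policy | None = None
) -> AuditReport:
    """Audit any payload produced by this package (or its serialized form).

    *raw*, when given, is the original data table (first two columns taken as
    the X, Y records) used for the coincidence check.
    """
    policy = policy or Policy()
    d = _payload_dict(payload)
    if d["kind"] not in _KNOWN_KINDS:
        raise SchemaError(f"unknown payload kind {d['kind']!r}")
    violations: list = []
    warnings_: list = []
    from_raw = d["method"] in _RAW_COUNT_METHODS

    # (a) small cell counts rule on everything the payload would render
    for loc, c in _exposed_counts(d):
        if 0 < c < policy.min_cell:
            finding = ("small-cell", loc, f"exposed count {c} below minimum {policy.min_cell}")
            (violations if from_raw else warnings_).append(finding)

    # (d) margin sensitivity on 2-D grids
    if d["kind"] in ("heatmap", "contour"):
        _grid_margin_checks(d, warnings_)

    # (c) support-bound escapes of anonymized values
    if policy.support_bounds:
        for label, x, y in _point_arrays(d):
            for var, values in (("X", x), ("Y", y)):
                if var in policy.support_bounds:
                    lo, hi = policy.support_bounds[var]
                    n_out = int(np.sum((values < lo) | (values > hi)))
                    if n_out:
                        warnings_.append(
                            (
                                "support-bounds",
                                f"{label}/{var}",
                                f"{n_out} anonymized values outside [{lo}, {hi}]",
                            )
                        )

    # (b) coincidence of anonymized points with raw records
    if raw is not None:
        rawx = raw.iloc[:, 0].to_numpy(dtype=float)
        rawy = raw.iloc[:, 1].to_numpy(dtype=float)
        tol = policy.coincidence_tol
        for label, x, y in _point_arrays(d):
            if len(x) == 0 or len(rawx) == 0:
                continue
            close = (np.abs(x[:, None] - rawx[None, :]) <= tol) & (
                np.abs(y[:, None] - rawy[None, :]) <= tol
            )
            for i in np.nonzero(close.any(axis=1))[0]:
                violations.append(
                    (
                        "coincidence",
                        f"{label} point {i}",
                        f"anonymized point within {tol} of a raw record",
                    )
                )

    return AuditReport(violations, warnings_)
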