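"""Parameter-space exploration: single-parameter scans and random sampling.

``single_parameter_scan`` varies one rate (or the copy number g) in
isolation, runs the plasmid-loss (or competitor) experiment per value and
tabulates R and T_p (or the steady fold-increase for competitor scans).

``random_sample`` draws parameter sets from a nine-dimensional box (g
stays fixed), runs the loss experiment for each and tabulates the metrics.
The synthesis/degradation pairs (alpha_m, alpha_s) and (beta_m, beta_s)
are drawn so that the log of their ratio is uniform over the achievable
range; the other five rates are uniform.  Every value is snapped to a
per-parameter resolution grid (anchored at the lower bound), and draws
violating alpha_m > beta_m or alpha_s > beta_s — the regime where mean
molecule numbers stay above one and a rate-equation description makes
sense — are redrawn.  Failed or unresolved runs are kept as flagged rows,
never dropped.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .competitor import competitor_fold_increase
from .integrate import IntegrationError, run_loss_experiment
from .metrics import peak_metrics
from .params import CircuitParams, CompetitorParams

__all__ = [
    "ScanSpec",
    "SampleSpec",
    "SweepTable",
    "TABLE_RANGES",
    "single_parameter_scan",
    "random_sample",
    "filter_region",
]

#: sampled box and resolution per parameter: name -> (min, max, resolution)
TABLE_RANGES = {
    "alpha_m": (0.001, 20.0, 0.0005),
    "beta_m": (0.001, 14.0, 0.0005),
    "alpha_s": (0.001, 20.0, 0.0005),
    "beta_s": (0.001, 14.0, 0.0005),
    "h_plus": (0.1, 200.0, 4.0),
    "h_minus": (0.001, 10.0, 0.005),
    "beta_c": (0.001, 2.0, 0.001),
    "alpha_p": (0.01, 30.0, 0.9),
    "beta_p": (0.001, 2.0, 0.02),
}

PARAM_COLUMNS = list(CircuitParams.FIELD_ORDER)


@dataclass(frozen=True)
class ScanSpec:
    """One-at-a-time scan of a single parameter."""

    parameter_name: str
    values: Tuple[float, ...]
    base: CircuitParams = CircuitParams()
    comp: Optional[CompetitorParams] = None
    experiment: str = "loss"
    t_event: float = 150.0
    t_end: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        valid = set(CircuitParams.FIELD_ORDER) | set(CompetitorParams.FIELD_ORDER)
        if self.parameter_name not in valid:
            raise ValueError(f"unknown parameter {self.parameter_name!r}")
        if not self.values:
            raise ValueError("values must be non-empty")
        if any(v < 0 for v in self.values):
            raise ValueError("scan values must be non-negative")
        if self.experiment not in ("loss", "competitor"):
            raise ValueError("experiment must be 'loss' or 'competitor'")
        if self.experiment == "competitor" and self.comp is None:
            raise ValueError("competitor scan requires CompetitorParams")


@dataclass(frozen=True)
class SampleSpec:
    """Constrained random sampling of the nine free rates (g fixed)."""

    n_samples: int = 4025
    seed: int = 0
    g: float = 6.0
    ranges: dict = field(default_factory=lambda: dict(TABLE_RANGES))
    t_loss: float = 150.0
    t_end: float = 300.0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name, (lo, hi, res) in self.ranges.items():
            if name not in TABLE_RANGES:
                raise ValueError(f"unknown parameter {name!r}")
            if not (0 <= lo <= hi) or res <= 0:
                raise ValueError(f"invalid range for {name!r}")
        # feasibility of the alpha > beta constraints within the boxes
        if not (self.ranges["alpha_m"][1] > self.ranges["beta_m"][0]
                and self.ranges["alpha_s"][1] > self.ranges["beta_s"][0]):
            raise ValueError("empty feasible region: alpha boxes lie below beta boxes")


@dataclass
class SweepTable:
    """Tidy table of parameter sets and their metrics, with provenance."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def ok(self) -> pd.DataFrame:
        """Rows whose run completed with a resolved, unflagged peak measurement."""
        return self.data[self.data["status"] == "ok"]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={v}\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SweepTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("# ") and "=" in line:
                    k, v = line[2:].rstrip("\n").split("=", 1)
                    meta[k] = v
                    pos = fh.tell()
                else:
                    break
            fh.seek(pos)
            data = pd.read_csv(fh, sep="\t")
        return cls(data=data, meta=meta)


def _spec_hash(spec) -> str:
    return hashlib.sha256(repr(spec).encode()).hexdigest()[:12]


def _metrics_row(traj, t_event):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pm = peak_metrics(traj, t_event, require_resolved=False)
    if not pm.resolved:
        return pm.R, math.nan, "unresolved"
    if pm.flagged:
        return pm.R, math.nan, "flagged"
    return pm.R, pm.T_p, "ok"


def single_parameter_scan(spec: ScanSpec, dt: float = 1e-4,
                          max_steps: int = 50_000_000) -> SweepTable:
    """Run one experiment per scan value; per-row failures are recorded, not raised."""
    rows = []
    for v in spec.values:
        if spec.parameter_name in CircuitParams.FIELD_ORDER:
            params = spec.base.replace(**{spec.parameter_name: v})
            comp = spec.comp
        else:
            params = spec.base
            comp = spec.comp.replace(**{spec.parameter_name: v})
        row = {name: getattr(params, name) for name in PARAM_COLUMNS}
        if comp is not None:
            row.update({name: getattr(comp, name)
                        for name in CompetitorParams.FIELD_ORDER})
        try:
            if spec.experiment == "loss":
                traj = run_loss_experiment(params, t_loss=spec.t_event,
                                           t_end=spec.t_end, dt=dt,
                                           max_steps=max_steps)
                R, T_p, status = _metrics_row(traj, spec.t_event)
            else:
                R = competitor_fold_increase(params, comp)
                T_p, status = math.nan, "ok"
        except (IntegrationError, ValueError) as exc:
            R, T_p, status = math.nan, math.nan, f"failed: {exc}"
        rows.append({**row, "R": R, "T_p": T_p, "status": status})
    data = pd.DataFrame(rows)
    meta = {"kind": f"scan:{spec.experiment}", "parameter": spec.parameter_name,
            "spec_hash": _spec_hash(spec),
            "n_failed": int((~data["status"].isin(["ok", "unresolved", "flagged"])).sum())}
    return SweepTable(data=data, meta=meta)


def _draw_log_ratio_pair(rng, lo_a, hi_a, lo_b, hi_b):
    """Draw (a, b) with log(a/b) uniform over its achievable range.

    b is then uniform over the values compatible with the drawn ratio and
    a = b * exp(u).
    """
    u = rng.uniform(math.log(lo_a / hi_b), math.log(hi_a / lo_b))
    b_lo = max(lo_b, lo_a * math.exp(-u))
    b_hi = min(hi_b, hi_a * math.exp(-u))
    b = rng.uniform(b_lo, b_hi)
    return b * math.exp(u), b


def _snap(v, lo, hi, res):
    return float(min(max(lo + round((v - lo) / res) * res, lo), hi))


def draw_parameter_sets(spec: SampleSpec, rng: np.random.Generator) -> List[CircuitParams]:
    """Draw ``spec.n_samples`` valid parameter sets (rejection on alpha > beta)."""
    r = spec.ranges
    out = []
    while len(out) < spec.n_samples:
        am, as_ = _draw_log_ratio_pair(rng, *r["alpha_m"][:2], *r["alpha_s"][:2])
        bm, bs = _draw_log_ratio_pair(rng, *r["beta_m"][:2], *r["beta_s"][:2])
        am = _snap(am, *r["alpha_m"])
        as_ = _snap(as_, *r["alpha_s"])
        bm = _snap(bm, *r["beta_m"])
        bs = _snap(bs, *r["beta_s"])
        if not (am > bm and as_ > bs):
            continue
        kw = {"alpha_m": am, "alpha_s": as_, "beta_m": bm, "beta_s": bs}
        for name in ("h_plus", "h_minus", "beta_c", "alpha_p", "beta_p"):
            lo, hi, res = r[name]
            kw[name] = _snap(rng.uniform(lo, hi), lo, hi, res)
        out.append(CircuitParams(g=spec.g, **kw))
    return out


def random_sample(spec: SampleSpec, dt: float = 1e-4,
                  max_steps: int = 20_000_000) -> SweepTable:
    """Sample the parameter box and measure the loss-experiment metrics per draw.

    Reproducible: identical spec (including seed) gives identical tables.
    Rows whose integration fails or whose peak cannot be resolved within the
    horizon keep their parameter values with NaN metrics and a status flag.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    n_failed = 0
    for params in draw_parameter_sets(spec, rng):
        row = {name: getattr(params, name) for name in PARAM_COLUMNS}
        try:
            traj = run_loss_experiment(params, t_loss=spec.t_loss,
                                       t_end=spec.t_end, dt=dt,
                                       max_steps=max_steps)
            R, T_p, status = _metrics_row(traj, spec.t_loss)
        except IntegrationError as exc:
            R, T_p, status = math.nan, math.nan, "failed"
            n_failed += 1
        rows.append({**row, "R": R, "T_p": T_p, "status": status})
    data = pd.DataFrame(rows)
    meta = {"kind": "random_sample", "seed": spec.seed, "n": spec.n_samples,
            "spec_hash": _spec_hash(spec), "n_failed": n_failed,
            "n_unresolved": int((data["status"] == "unresolved").sum())}
    return SweepTable(data=data, meta=meta)


def _eval_expr(data: pd.DataFrame, expr: str) -> pd.Series:
    """Evaluate ``[coef*]column[/column]`` over the table columns."""
    expr = expr.replace(" ", "")
    coef = 1.0
    if "*" in expr:
        head, expr = expr.split("*", 1)
        coef = float(head)
    if "/" in expr:
        num, den = expr.split("/", 1)
        for name in (num, den):
            if name not in data.columns:
                raise ValueError(f"unknown column {name!r}")
        return coef * data[num] / data[den]
    if expr not in data.columns:
        raise ValueError(f"unknown column {expr!r}")
    return coef * data[expr]


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
}


def filter_region(table: SweepTable,
                  predicates: Sequence[Tuple[str, str, float]]) -> SweepTable:
    """Sub-table of rows satisfying all ``(expression, comparison, bound)`` predicates.

    Expressions are single columns, ratios of columns, optionally with a
    leading numeric coefficient — e.g. ``("alpha_m/alpha_s", "<", 0.8)`` or
    ``("1.5*beta_c", "<", 1.0)``.
    """
    mask = pd.Series(True, index=table.data.index)
    for expr, op, bound in predicates:
        if op not in _OPS:
            raise ValueError(f"unknown comparison {op!r}")
        mask &= _OPS[op](_eval_expr(table.data, expr), float(bound))
    meta = dict(table.meta)
    meta["filtered"] = "; ".join(f"{e}{op}{b}" for e, op, b in predicates) or "none"
    return SweepTable(data=table.data[mask].reset_index(drop=True), meta=meta)
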