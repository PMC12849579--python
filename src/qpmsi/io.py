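"""File readers/writers, run configuration and the comparison pipeline.

CSV dialects (comma-separated, header row required, UTF-8, "." decimal,
genotype ids read as strings):

traits      first column = genotype id, remaining columns = trait BLUEs
markers     first column = genotype id, remaining columns = marker
            dosages (TSV accepted for ``.tsv``/``.txt`` extensions)
grm         square; first row and first column carry the genotype ids

``run_compare`` reproduces the standard method comparison: the linear
index (LPMSI) once plus the quadratic index (QPMSI) at every ``k`` in a
grid, each evaluated with the M/V/MV/MR metrics plus the four
relative-efficiency tables.  Infeasible runs appear in the report with
blank metrics and a logged recommendation to fall back to the linear
index — infeasibility is a result, not an error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import IDMismatch, InvalidConfig, ParseError
from .grm import MarkerMatrix, RelationshipMatrix, compute_grm, validate_grm
from .metrics import EfficiencyReport, MetricsReport, compute_metrics, relative_efficiency
from .optimize import (
    SelectionProblem,
    SelectionResult,
    SelectionSpec,
    build_problem,
    solve_lpmsi,
    solve_qpmsi,
)
from .preprocess import TraitTable, standardize_and_adjust

logger = logging.getLogger(__name__)

METRIC_NAMES = ("M", "V", "MV", "MR")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype={0: str}, index_col=0)
    except Exception as exc:  # pandas raises many flavors; unify
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found")
    df.index = df.index.astype(str)
    return df


def read_trait_table(path: str | Path, directions=None) -> TraitTable:
    """Load a trait BLUE CSV; ``directions`` defaults to all higher-is-better."""
    df = _read_table(path)
    values = df.to_numpy(dtype=float)
    return TraitTable(
        tuple(df.index), values, tuple(df.columns),
        tuple(directions) if directions else (),
    )


def read_marker_matrix(path: str | Path) -> MarkerMatrix:
    """Load a marker dosage CSV/TSV."""
    df = _read_table(path)
    return MarkerMatrix(tuple(df.index), df.to_numpy(dtype=float), tuple(df.columns))


def read_grm(path: str | Path) -> RelationshipMatrix:
    """Load and validate a precomputed square relationship matrix CSV."""
    df = _read_table(path)
    if list(df.index) != list(df.columns):
        if set(df.index) != set(df.columns):
            raise ParseError(f"{path}: row and column id sets differ")
        df = df.loc[df.index, df.index]
    return validate_grm(tuple(df.index), df.to_numpy(dtype=float))


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    pd.DataFrame(
        traits.values, index=list(traits.genotype_ids), columns=list(traits.trait_names)
    ).rename_axis("genotype").to_csv(path)


def write_marker_matrix(markers: MarkerMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(
        markers.dosages, index=list(markers.genotype_ids), columns=list(markers.marker_names)
    ).rename_axis("genotype").to_csv(path, sep=sep)


def write_grm(G: RelationshipMatrix, path: str | Path) -> None:
    ids = list(G.genotype_ids)
    pd.DataFrame(G.G, index=ids, columns=ids).rename_axis("genotype").to_csv(path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run (YAML/JSON loadable).

    Exactly one of ``markers`` / ``grm`` must be given; the GRM is
    computed from markers or loaded/validated from file accordingly.
    """

    traits: str
    s: int
    markers: str | None = None
    grm: str | None = None
    out_dir: str = "."
    k_grid: tuple[float, ...] = (0.5, 1.0, 1.5)
    R: tuple[float, ...] = ()
    directions: tuple[str, ...] = ()
    scaling: str = "column_standardize"
    method: str = "exact_milp"
    sd_ddof: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.markers is None) == (self.grm is None):
            raise InvalidConfig("exactly one of 'markers' or 'grm' must be provided")
        kg = tuple(float(k) for k in self.k_grid)
        if not kg or any(k < 0 for k in kg):
            raise InvalidConfig("k_grid must be non-empty with all k >= 0")
        object.__setattr__(self, "k_grid", kg)
        object.__setattr__(self, "R", tuple(float(r) for r in self.R))
        object.__setattr__(self, "directions", tuple(self.directions))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfig(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def load_inputs(config: RunConfig) -> SelectionProblem:
    """Read, align and assemble a selection problem from a run config.

    Genotype ids present in only one input are dropped (intersection,
    with a logged warning); the trait table's order defines the common
    order.  Raises :class:`IDMismatch` when the intersection is empty.
    """
    traits = read_trait_table(config.traits, config.directions or None)
    if config.markers is not None:
        markers = read_marker_matrix(config.markers)
        G = compute_grm(markers, config.scaling)  # type: ignore[arg-type]
    else:
        G = read_grm(config.grm)

    t_ids, g_ids = set(traits.genotype_ids), set(G.genotype_ids)
    common = [g for g in traits.genotype_ids if g in g_ids]
    if not common:
        raise IDMismatch("no genotype ids shared between traits and relationship matrix")
    dropped = sorted((t_ids | g_ids) - set(common))
    if dropped:
        logger.warning("dropping %d genotype(s) absent from one input: %s",
                       len(dropped), dropped[:20])
        keep = [i for i, g in enumerate(traits.genotype_ids) if g in g_ids]
        traits = TraitTable(
            tuple(common), traits.values[keep], traits.trait_names, traits.directions
        )
    G = validate_grm(G.genotype_ids, G.G, id_order=common)

    y = standardize_and_adjust(traits, ddof=config.sd_ddof)
    spec = SelectionSpec(s=config.s, k=config.k_grid[0], R=config.R)
    return build_problem(y, G, spec)


# ---------------------------------------------------------------------------
# comparison pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodRow:
    """One (method, k) row of a comparison report."""

    label: str
    method: str
    k: float | None
    result: SelectionResult
    metrics: MetricsReport | None


@dataclass(frozen=True)
class ComparisonReport:
    """All rows plus one relative-efficiency table per metric."""

    rows: tuple[MethodRow, ...]
    efficiencies: dict[str, EfficiencyReport] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            m = row.metrics
            recs.append({
                "Method": row.method, "k": row.k, "status": row.result.status,
                "M": m.M if m else np.nan, "V": m.V if m else np.nan,
                "MV": (m.MV if m and m.MV is not None else np.nan),
                "MR": (m.MR if m and m.MR is not None else np.nan),
            })
        return pd.DataFrame.from_records(recs)

    def as_dict(self) -> dict:
        out = {"rows": [], "efficiencies": {}}
        for row in self.rows:
            r = row.result
            out["rows"].append({
                "label": row.label, "method": row.method, "k": row.k,
                "status": r.status, "solver": r.solver,
                "selected_ids": list(r.selected_ids),
                "objective": None if np.isnan(r.objective) else r.objective,
                "merit_term": None if np.isnan(r.merit_term) else r.merit_term,
                "penalty_term": None if np.isnan(r.penalty_term) else r.penalty_term,
                "metrics": row.metrics.as_dict() if row.metrics else None,
            })
        for name, eff in self.efficiencies.items():
            out["efficiencies"][name] = {
                "best": eff.best_label, "RE_percent": eff.RE, "flags": eff.flags,
            }
        return out


def run_compare(config: RunConfig, *, write: bool = True) -> ComparisonReport:
    """Run LPMSI plus QPMSI over the k-grid and compare with all metrics.

    Writes ``report.json``, ``metrics.csv`` and one ``selected_<label>.txt``
    per feasible method under ``config.out_dir`` unless ``write=False``.
    Output is a pure function of (config, inputs): rerunning with the
    same config yields byte-identical reports.
    """
    problem = load_inputs(config)
    rows: list[MethodRow] = []

    lp = solve_lpmsi(problem)
    rows.append(_make_row("LPMSI", "LPMSI", None, lp, problem))
    for k in config.k_grid:
        spec_k = dataclasses.replace(problem.spec, k=k)
        prob_k = dataclasses.replace(problem, spec=spec_k)
        res = solve_qpmsi(prob_k, method=config.method, seed=config.seed)  # type: ignore[arg-type]
        if res.status == "infeasible":
            logger.warning(
                "QPMSI infeasible at k=%g (%s); the linear index (LPMSI) "
                "should be used as an alternative", k, res.message,
            )
        rows.append(_make_row(f"QPMSI_k{k:g}", "QPMSI", k, res, problem))

    efficiencies: dict[str, EfficiencyReport] = {}
    for name in METRIC_NAMES:
        values = {
            row.label: getattr(row.metrics, name) if row.metrics else None
            for row in rows
        }
        finite = [v for v in values.values() if v is not None and np.isfinite(v)]
        if len(finite) >= 2:
            efficiencies[name] = relative_efficiency(values, name)  # type: ignore[arg-type]

    report = ComparisonReport(rows=tuple(rows), efficiencies=efficiencies)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        report.metrics_frame().to_csv(out / "metrics.csv", index=False, float_format="%.6g")
        for row in report.rows:
            if row.result.selected_ids:
                (out / f"selected_{row.label}.txt").write_text(
                    "\n".join(row.result.selected_ids) + "\n", encoding="utf-8"
                )
    return report


def _make_row(
    label: str, method: str, k: float | None,
    result: SelectionResult, problem: SelectionProblem,
) -> MethodRow:
    metrics = None
    if result.status in ("optimal", "heuristic"):
        metrics = compute_metrics(result, problem.y, problem.G, method_label=label)
    return MethodRow(label=label, method=method, k=k, result=result, metrics=metrics)
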