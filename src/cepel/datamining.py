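"""Fully automatic relation discovery on tabular data.

Every column is typed continuous or discrete, every single-column
distribution is estimated, and every pair of columns is scored by fitting the
applicable 1d-decomposition models and comparing their normalised
leave-one-out log-likelihoods:

- continuous x continuous: the model zoo (naive Bayes, regression,
  eigenvectors, radial, and logarithmic where the abscissa is positive); the
  relation strength is the winner's margin over the independence model
  (naive Bayes);
- continuous x discrete: a conditional model (one kernel density per class,
  weighted by the class probability) against the class-blind single density;
- discrete x discrete: the joint probability table against the product of
  the marginals.

The analysis needs no parameter setting: pairs whose margin falls below a
small floor are reported as "no relation found", everything else is ranked
by margin.  Reports are produced as JSON and as a self-contained HTML page.
"""

from __future__ import annotations

import base64
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kde1d import (DEFAULT_CONFIG, KDEConfig, Sample1D, ValidationError,
                    find_modes, fit_discrete, fit_kde1d)
from .models import CepelModel, Component
from .projections import Projection
from .selection import rank_models

__all__ = [
    "Column",
    "Relation",
    "infer_column_kind",
    "column_from_series",
    "build_conditional_model",
    "analyze_pair",
    "analyze_table",
    "report_json",
    "report_html",
]

MARGIN_FLOOR = 0.02   # nats per dimension: below this a pair is "no relation"
MIN_PAIR_ROWS = 20
_FLOOR = 1e-300


@dataclass
class Column:
    name: str
    kind: str                    # "continuous" | "discrete"
    values: np.ndarray           # float with NaN missing, or object with None
    missing: np.ndarray          # boolean mask

    @property
    def clean(self) -> np.ndarray:
        return self.values[~self.missing]

    @property
    def n(self) -> int:
        return int((~self.missing).sum())


def infer_column_kind(values) -> str:
    """Type a column: discrete iff non-numeric, or integer-valued with at
    most max(10, sqrt(N)) distinct values; continuous otherwise."""
    vals = pd.Series(list(values)).dropna()
    if vals.empty:
        raise ValidationError("all values missing")
    numeric = pd.to_numeric(vals, errors="coerce")
    if numeric.isna().any():
        return "discrete"
    numeric = numeric.astype(float)
    distinct = numeric.nunique()
    if np.allclose(numeric, np.round(numeric)) and \
            distinct <= max(10, np.sqrt(len(numeric))):
        return "discrete"
    return "continuous"


def column_from_series(name: str, series: pd.Series) -> Column:
    kind = infer_column_kind(series)
    if kind == "continuous":
        vals = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
        missing = ~np.isfinite(vals)
    else:
        missing = series.isna().to_numpy()
        vals = series.astype(object).to_numpy()
    return Column(name=name, kind=kind, values=vals, missing=missing)


@dataclass
class Relation:
    pair: tuple[str, str]
    kind: str                    # "cc" | "cd" | "dd"
    winner: str
    score: float
    margin: float                # winner minus independence baseline
    n: int
    scores: list = field(default_factory=list)      # (name, score) runner-ups
    skipped_models: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"pair": list(self.pair), "kind": self.kind,
                "model": self.winner, "score": round(self.score, 6),
                "margin": round(self.margin, 6), "n": self.n,
                "scores": [[n, round(s, 6)] for n, s in self.scores],
                "skipped_models": self.skipped_models}


# ---------------------------------------------------------------------------
# Conditional (continuous x discrete) and discrete x discrete scoring
# ---------------------------------------------------------------------------


def build_conditional_model(x: np.ndarray, classes: np.ndarray,
                            config: KDEConfig = DEFAULT_CONFIG) -> CepelModel:
    """A conditional model over points (x, class code): the class value
    selects a per-class density, weighted by the class probability."""
    pmf = fit_discrete(classes.tolist())
    codes = np.array([pmf.categories.index(c) for c in classes], dtype=float)
    comps = []
    for k, cat in enumerate(pmf.categories):
        xs = x[codes == k]
        comps.append(Component(Projection("axis", {"index": 0}),
                               fit_kde1d(Sample1D(xs), config), label=float(k)))
    from .kde1d import DiscretePMF
    code_pmf = DiscretePMF(tuple(float(k) for k in range(len(pmf.categories))),
                           pmf.probabilities)
    return CepelModel(components=tuple(comps), combiner="conditional",
                      dimensionality=2, class_axis=1, class_pmf=code_pmf,
                      name="conditional",
                      meta={"categories": list(pmf.categories)})


def _conditional_vs_blind(x: np.ndarray, classes: np.ndarray,
                          config: KDEConfig) -> tuple[float, float]:
    """Normalised LOO scores of the conditional model and the class-blind
    (independence) model on (x, class) data.

    Both use kernel-level LOO for the density factor and a leave-one-out
    class frequency for the discrete factor; densities are normalised over
    the padded data interval.
    """
    n = x.size
    lo, hi = float(x.min()), float(x.max())
    pad = 0.05 * max(hi - lo, 1e-12)
    lo, hi = lo - pad, hi + pad
    cats, codes = np.unique(classes.astype(str), return_inverse=True)
    counts = np.bincount(codes, minlength=len(cats))

    blind_dens = fit_kde1d(Sample1D(x), config)
    z_blind = 1.0 / max(blind_dens.integrate(lo, hi), _FLOOR)
    blind_loo = blind_dens.loo_density_at_fit_points() * z_blind

    cond_loo = np.empty(n)
    for k in range(len(cats)):
        mask = codes == k
        xs = x[mask]
        if np.unique(xs).size < 2:
            raise ValidationError(
                f"class {cats[k]!r} has fewer than 2 distinct values")
        dens = fit_kde1d(Sample1D(xs), config)
        z = 1.0 / max(dens.integrate(lo, hi), _FLOOR)
        cond_loo[mask] = dens.loo_density_at_fit_points() * z

    pmf_loo = (counts[codes] - 1) / (n - 1)
    pmf_loo = np.maximum(pmf_loo, 0.5 / (n - 1))
    cond = float(np.mean(np.log(np.maximum(cond_loo * pmf_loo, _FLOOR)))) / 2.0
    blind = float(np.mean(np.log(np.maximum(blind_loo * pmf_loo, _FLOOR)))) / 2.0
    return cond, blind


def _joint_vs_product(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """LOO scores of the joint PMF and the product-of-marginals PMF."""
    n = a.size
    a_codes = pd.factorize(a.astype(str))[0]
    b_codes = pd.factorize(b.astype(str))[0]
    joint = {}
    for i in range(n):
        joint[(a_codes[i], b_codes[i])] = joint.get((a_codes[i], b_codes[i]), 0) + 1
    na = np.bincount(a_codes)
    nb = np.bincount(b_codes)
    floor = 0.5 / (n - 1)
    j_loo = np.array([max((joint[(a_codes[i], b_codes[i])] - 1) / (n - 1), floor)
                      for i in range(n)])
    p_loo = (np.maximum((na[a_codes] - 1) / (n - 1), floor)
             * np.maximum((nb[b_codes] - 1) / (n - 1), floor))
    joint_score = float(np.mean(np.log(j_loo))) / 2.0
    prod_score = float(np.mean(np.log(p_loo))) / 2.0
    return joint_score, prod_score


# ---------------------------------------------------------------------------
# Pair analysis
# ---------------------------------------------------------------------------


def analyze_pair(a: Column, b: Column, config: KDEConfig = DEFAULT_CONFIG,
                 seed: int = 0) -> Relation:
    """Score the relation between two columns by model comparison.

    Missing values are removed pairwise.  Raises ValidationError when the
    pair is degenerate (too few complete rows, constant columns, classes too
    small) — analyze_table converts that into a skipped entry.
    """
    ok = ~(a.missing | b.missing)
    if ok.sum() < MIN_PAIR_ROWS:
        raise ValidationError(
            f"only {int(ok.sum())} complete rows (need {MIN_PAIR_ROWS})")
    n = int(ok.sum())

    if a.kind == "continuous" and b.kind == "continuous":
        x = a.values[ok].astype(float)
        y = b.values[ok].astype(float)
        data = np.column_stack([x, y])
        candidates = ["naive_bayes", "regression", "eigenvectors", "radial"]
        if x.min() > 0:
            candidates.append("logarithmic")
        ranked, skipped = rank_models(candidates, data, config, seed=seed)
        by_name = {s.name: s.normalized_loo_loglik for s in ranked}
        if "naive_bayes" not in by_name:
            raise ValidationError("independence baseline failed to fit")
        win = ranked[0]
        return Relation(
            pair=(a.name, b.name), kind="cc", winner=win.name,
            score=win.normalized_loo_loglik,
            margin=win.normalized_loo_loglik - by_name["naive_bayes"],
            n=n,
            scores=[(s.name, s.normalized_loo_loglik) for s in ranked],
            skipped_models=[list(s) for s in skipped])

    if a.kind != b.kind:
        cont, disc = (a, b) if a.kind == "continuous" else (b, a)
        x = cont.values[ok].astype(float)
        classes = disc.values[ok]
        counts = pd.Series(classes.astype(str)).value_counts()
        if (counts < 5).any():
            raise ValidationError(
                f"class {counts.idxmin()!r} has fewer than 5 rows")
        if np.unique(x).size < 2 or len(counts) < 2:
            raise ValidationError("degenerate column in pair")
        cond, blind = _conditional_vs_blind(x, classes, config)
        winner = "conditional" if cond > blind else "independent"
        return Relation(
            pair=(a.name, b.name), kind="cd", winner=winner,
            score=max(cond, blind), margin=cond - blind, n=n,
            scores=[("conditional", cond), ("independent", blind)])

    av, bv = a.values[ok], b.values[ok]
    if pd.Series(av.astype(str)).nunique() < 2 or \
            pd.Series(bv.astype(str)).nunique() < 2:
        raise ValidationError("degenerate discrete column in pair")
    joint, prod = _joint_vs_product(av, bv)
    winner = "joint" if joint > prod else "independent"
    return Relation(pair=(a.name, b.name), kind="dd", winner=winner,
                    score=max(joint, prod), margin=joint - prod, n=n,
                    scores=[("joint", joint), ("independent", prod)])


# ---------------------------------------------------------------------------
# Whole-table analysis and reports
# ---------------------------------------------------------------------------


def _column_summary(col: Column, config: KDEConfig) -> dict:
    out = {"name": col.name, "kind": col.kind, "n": col.n,
           "missing": int(col.missing.sum())}
    if col.kind == "discrete":
        pmf = fit_discrete(col.clean.tolist())
        out["pmf"] = {str(c): round(float(p), 6) for c, p in
                      zip(pmf.categories, pmf.probabilities)}
    else:
        vals = col.clean.astype(float)
        out["mean"] = float(np.mean(vals))
        out["std"] = float(np.std(vals))
        if np.unique(vals).size >= 2:
            dens = fit_kde1d(Sample1D(vals), config)
            out["modes"] = [round(m, 6) for m in find_modes(dens)]
            out["bandwidth"] = float(dens.global_bandwidth)
    return out


def analyze_table(table, seed: int = 0, margin_floor: float = MARGIN_FLOOR,
                  config: KDEConfig = DEFAULT_CONFIG) -> dict:
    """Fully automatic analysis of a table (DataFrame or CSV path).

    Returns a report structure with per-column distribution summaries, all
    pair relations ranked by the margin of the winning model over the
    independence model, pairs with no relation found, and skipped pairs with
    reasons.  Every pair of usable columns is either scored or listed as
    skipped.
    """
    if not isinstance(table, pd.DataFrame):
        from .io import read_table
        table = read_table(table)
    columns, skipped_cols = [], []
    for name in table.columns:
        series = table[name]
        try:
            col = column_from_series(str(name), series)
        except ValidationError as exc:
            skipped_cols.append({"column": str(name), "reason": str(exc)})
            continue
        if col.n < 2:
            skipped_cols.append({"column": str(name), "reason": "too few values"})
            continue
        if col.kind == "continuous" and np.unique(col.clean).size < 2:
            skipped_cols.append({"column": str(name), "reason": "constant column"})
            continue
        columns.append(col)

    summaries = [_column_summary(c, config) for c in columns]
    relations, no_relation, skipped_pairs = [], [], []
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            a, b = columns[i], columns[j]
            try:
                rel = analyze_pair(a, b, config, seed=seed)
            except ValidationError as exc:
                skipped_pairs.append({"pair": [a.name, b.name],
                                      "reason": str(exc)})
                continue
            if rel.margin >= margin_floor:
                relations.append(rel)
            else:
                no_relation.append(rel)
    relations.sort(key=lambda r: -r.margin)
    no_relation.sort(key=lambda r: -r.margin)
    return {
        "seed": seed,
        "margin_floor": margin_floor,
        "columns": summaries,
        "relations": [r.as_dict() for r in relations],
        "no_relation": [r.as_dict() for r in no_relation],
        "skipped": skipped_pairs + skipped_cols,
    }


def report_json(report: dict, path=None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _fig_to_b64(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80)
    import matplotlib.pyplot as plt
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def report_html(report: dict, table: pd.DataFrame, path=None,
                config: KDEConfig = DEFAULT_CONFIG) -> str:
    """Self-contained HTML report with embedded plots of the distributions
    and the discovered relations."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    parts = ["<html><head><meta charset='utf-8'><title>Cepel report</title>",
             "<style>body{font-family:sans-serif;max-width:1000px;margin:auto}"
             "img{border:1px solid #ccc;margin:4px}</style></head><body>",
             "<h1>Automatic data analysis</h1>"]
    parts.append(f"<p>{len(report['columns'])} columns analysed; "
                 f"{len(report['relations'])} relations found "
                 f"(margin floor {report['margin_floor']}).</p>")

    parts.append("<h2>Column distributions</h2>")
    for summary in report["columns"]:
        name = summary["name"]
        fig, ax = plt.subplots(figsize=(4, 2.6))
        if summary["kind"] == "discrete":
            pmf = summary["pmf"]
            ax.bar(range(len(pmf)), list(pmf.values()))
            ax.set_xticks(range(len(pmf)), list(pmf.keys()), rotation=45)
            ax.set_ylabel("probability")
        else:
            vals = pd.to_numeric(table[name], errors="coerce").dropna().to_numpy()
            dens = fit_kde1d(Sample1D(vals), config)
            grid = dens.grid()
            ax.plot(grid, dens(grid))
            ax.set_ylabel("density")
        ax.set_title(f"{name} ({summary['kind']})", fontsize=9)
        fig.tight_layout()
        parts.append(f"<img src='data:image/png;base64,{_fig_to_b64(fig)}'/>")

    parts.append("<h2>Relations (strongest first)</h2>")
    if not report["relations"]:
        parts.append("<p>No relations above the margin floor.</p>")
    for rel in report["relations"]:
        na, nb = rel["pair"]
        parts.append(f"<h3>{na} &mdash; {nb}: {rel['model']} "
                     f"(margin {rel['margin']:.3f} nats/dim)</h3>")
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        sa = pd.to_numeric(table[na], errors="coerce")
        sb = pd.to_numeric(table[nb], errors="coerce")
        if rel["kind"] == "cc":
            ax.scatter(sa, sb, s=6, alpha=0.5)
            ax.set_xlabel(na)
            ax.set_ylabel(nb)
        elif rel["kind"] == "cd":
            cont, disc = (na, nb) if sa.notna().all() else (nb, na)
            x = pd.to_numeric(table[cont], errors="coerce")
            for cls, sub in table.groupby(disc):
                vals = pd.to_numeric(sub[cont], errors="coerce").dropna().to_numpy()
                if np.unique(vals).size < 2:
                    continue
                dens = fit_kde1d(Sample1D(vals), config)
                grid = dens.grid()
                ax.plot(grid, dens(grid), label=str(cls))
            ax.legend(fontsize=7)
            ax.set_xlabel(cont)
            ax.set_ylabel("density")
        else:
            ct = pd.crosstab(table[na], table[nb], normalize=True)
            ax.imshow(ct.to_numpy(), cmap="Blues")
            ax.set_xticks(range(ct.shape[1]), [str(c) for c in ct.columns],
                          rotation=45)
            ax.set_yticks(range(ct.shape[0]), [str(c) for c in ct.index])
        fig.tight_layout()
        parts.append(f"<img src='data:image/png;base64,{_fig_to_b64(fig)}'/>")

    parts.append("</body></html>")
    text = "\n".join(parts)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
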