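"""Group-comparison statistics and the end-to-end analysis pipeline.

Two-sample contrasts are computed from group summary statistics (n, mean,
SD): the classical pooled-variance t with df = n1 + n2 - 2, and the Welch
t with Welch–Satterthwaite df.  Two effect sizes are always reported with
explicit labels, because the literature mixes them under the name "d":

* ``d_pooled``  — Cohen's d, mean difference over the pooled SD;
* ``r_from_t``  — the r-type effect size sqrt(t^2 / (t^2 + df)).

``run_pipeline`` wires the whole analysis together: synthesize a cohort,
compute behavioral metrics, profile and group subjects by their aSCR
index, fit the PVL model (MLE per subject; hierarchical Bayes optional),
and run the planned group contrasts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .behavior_metrics import metrics_table
from .estimation import fit_hba, fit_mle, fits_table
from .scr_pipeline import ASCRProfile, GROUP_NEG, GROUP_POS, profile_table
from .synthetic_cohort import CohortSpec, generate_cohort


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=v.size, mean=float(v.mean()), sd=float(v.std(ddof=1)), label=label)


@dataclass(frozen=True)
class ContrastResult:
    t: float
    df: float
    p: float
    d_pooled: float
    r_from_t: float
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


def effect_sizes(t: float, df: float, g1: GroupSummary, g2: GroupSummary) -> tuple[float, float]:
    """(d_pooled, r_from_t) for a two-sample contrast."""
    if df <= 0:
        raise ValueError("df must be positive")
    sp = _pooled_sd(g1, g2)
    d = abs(g1.mean - g2.mean) / sp if sp > 0 else 0.0
    r = float(np.sqrt(t**2 / (t**2 + df)))
    return float(d), r


def _pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    num = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    return float(np.sqrt(num / (g1.n + g2.n - 2)))


def pooled_t(g1: GroupSummary, g2: GroupSummary) -> ContrastResult:
    """Classical pooled-variance two-sample t test from summaries."""
    df = g1.n + g2.n - 2
    sp = _pooled_sd(g1, g2)
    se = sp * np.sqrt(1.0 / g1.n + 1.0 / g2.n)
    if se == 0:
        if g1.mean == g2.mean:
            t = 0.0
        else:
            raise ValueError("zero variance in both groups with different means")
    else:
        t = (g1.mean - g2.mean) / se
    p = float(2 * sps.t.sf(abs(t), df))
    d, r = effect_sizes(t, df, g1, g2)
    return ContrastResult(t=float(t), df=float(df), p=p, d_pooled=d, r_from_t=r, method="pooled")


def welch_t(g1: GroupSummary, g2: GroupSummary) -> ContrastResult:
    """Welch two-sample t with Welch–Satterthwaite df, from summaries."""
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("zero variance in both groups: Welch t undefined")
    t = (g1.mean - g2.mean) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    d, r = effect_sizes(float(t), float(df), g1, g2)
    return ContrastResult(t=float(t), df=float(df), p=p, d_pooled=d, r_from_t=r, method="welch")


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p values, keyed like the input."""
    from statsmodels.stats.multitest import multipletests

    keys = list(pvalues)
    _, adj, _, _ = multipletests([pvalues[k] for k in keys], method="holm")
    return dict(zip(keys, (float(a) for a in adj)))


# ---------------------------------------------------------------------------
# Pipeline


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "rule": "decay",
    "mle": {"enabled": True, "n_starts": 20},
    "hba": {"enabled": False, "chains": 4, "iterations": 500, "warmup": 1500,
            "mode": "per_group"},  # or "joint"
    "holm": False,
    "outdir": None,
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None = None, spec: CohortSpec | None = None) -> dict:
    """Execute generate -> metrics -> aSCR grouping -> fits -> contrasts.

    Returns a report bundle (dict); if ``config['outdir']`` is set, CSV
    tables and a JSON report are written there.  Deterministic under
    ``config['seed']``.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    stage = "generate"
    try:
        cohort = generate_cohort(spec or CohortSpec(rule=cfg["rule"]), seed=cfg["seed"])
        sessions = cohort.sessions()

        stage = "metrics"
        metrics = metrics_table(sessions)

        stage = "scr"
        profiles = [
            ASCRProfile.from_trace(s.trace, s.session.choices, subject_id=s.subject_id)
            for s in cohort.subjects
        ]
        prof_df = profile_table(profiles)
        merged = metrics.merge(prof_df, on="subject_id")

        stage = "fit-mle"
        mle_df = None
        if cfg["mle"]["enabled"]:
            fits = [
                fit_mle(s, rule=cfg["rule"], n_starts=cfg["mle"]["n_starts"], seed=cfg["seed"])
                for s in sessions
            ]
            mle_df = fits_table(fits, subject_ids=[s.subject_id for s in cohort.subjects])
            merged = merged.merge(mle_df.rename(columns={
                "alpha": "mle_alpha", "lam": "mle_lam", "A": "mle_A", "c": "mle_c",
                "loglik": "mle_loglik"}).drop(columns=["rule", "n_starts", "converged"]),
                on="subject_id")

        stage = "fit-hba"
        hba_out = None
        if cfg["hba"]["enabled"]:
            hba_out = {}
            h = cfg["hba"]
            if h["mode"] == "joint":
                groupings = {"all": list(range(len(sessions)))}
            else:
                groupings = {
                    g: [i for i, p in enumerate(profiles) if p.group_label == g]
                    for g in (GROUP_NEG, GROUP_POS)
                }
            for gname, idxs in groupings.items():
                if len(idxs) < 2:
                    continue
                summ = fit_hba(
                    [sessions[i] for i in idxs],
                    rule=cfg["rule"],
                    chains=h["chains"],
                    iterations=h["iterations"],
                    warmup=h["warmup"],
                    seed=cfg["seed"],
                )
                hba_out[gname] = json.loads(summ.to_json())

        stage = "contrasts"
        contrasts: dict[str, dict] = {}
        variables = ["total_gi", "adv", "ascr_index_uS"]
        if mle_df is not None:
            variables += ["mle_alpha", "mle_lam", "mle_A", "mle_c"]
        by_group = {g: merged[merged["group"] == g] for g in (GROUP_NEG, GROUP_POS)}
        if all(len(df) >= 2 for df in by_group.values()):
            for var in variables:
                g1 = GroupSummary.from_values(by_group[GROUP_NEG][var], GROUP_NEG)
                g2 = GroupSummary.from_values(by_group[GROUP_POS][var], GROUP_POS)
                contrasts[var] = {
                    "groups": {GROUP_NEG: asdict(g1), GROUP_POS: asdict(g2)},
                    "pooled": pooled_t(g1, g2).to_dict(),
                    "welch": welch_t(g1, g2).to_dict(),
                }
            if cfg["holm"]:
                adj = holm_adjust({v: contrasts[v]["pooled"]["p"] for v in contrasts})
                for v, padj in adj.items():
                    contrasts[v]["pooled"]["p_holm"] = padj
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = {
        "seed": cfg["seed"],
        "rule": cfg["rule"],
        "n_subjects": len(cohort.subjects),
        "groups": {
            g: int((merged["group"] == g).sum())
            for g in sorted(merged["group"].unique())
        },
        "contrasts": contrasts,
        "hba": hba_out,
        "config": {k: cfg[k] for k in ("seed", "rule", "mle", "hba", "holm")},
    }

    if cfg["outdir"]:
        outdir = Path(cfg["outdir"])
        outdir.mkdir(parents=True, exist_ok=True)
        merged.to_csv(outdir / "subjects.csv", index=False)
        if mle_df is not None:
            mle_df.to_csv(outdir / "mle_fits.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        report["files"] = {
            "subjects.csv": _sha256(outdir / "subjects.csv"),
            "report.json": _sha256(outdir / "report.json"),
        }
    report["tables"] = {"subjects": merged, "mle": mle_df}
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
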