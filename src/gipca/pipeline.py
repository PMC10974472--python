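"""End-to-end orchestration: features -> PCA -> bootstrapped mean-score
clouds -> Jaccard overlap -> GMM classification, with a reproducible run
report.

The pipeline accepts either a labelled feature table (the direct path) or a
set of raw force-plate trial files (the kinetics path).  A single global
seed deterministically derives independent substreams for the two groups'
bootstraps and for each subspace's mixture fit, so a run is reproducible
bit-for-bit from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import align_and_confuse, classify, fit_gmm
from .decomposition import PCAModel, fit_pca, project
from .kinetics import TrialRecording, extract_features
from .registry import GROUPS
from .resampling import BootstrapCloud, bootstrap_means, jaccard_overlap

DEFAULT_CONFIG: dict[str, object] = {
    "seed": 0,
    "filter.fc": 10.0,
    "filter.order": 2,
    "events.k_sigma": 2.5,
    "events.min_sustain_ms": 50.0,
    "events.baseline_s": 0.5,
    "pca.var_threshold": 0.999,
    "bootstrap.B": 10_000,
    "ellipse.level": 0.95,
    "jaccard.method": "membership",
    "gmm.K": 2,
    "gmm.tol": 1e-8,
    "gmm.max_iter": 500,
    "gmm.n_init": 10,
    "gmm.reg_floor": 1e-8,
    "subspaces": "1,2;2,3",
    "simplify.drop_tol": 0.1,
    "simplify.merge_tol": 0.2,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Flat dotted-key configuration with defaults for every key."""

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        merged = dict(DEFAULT_CONFIG)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])  # type: ignore[arg-type]

    def subspace_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for chunk in str(self.values["subspaces"]).split(";"):
            i, j = (int(s) for s in chunk.split(","))
            if i < 1 or j < 1 or i == j:
                raise ValueError(f"bad subspace pair {chunk!r}")
            pairs.append((i, j))
        return pairs

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file (# starts a comment)."""
        values: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"cannot parse config line {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in DEFAULT_CONFIG:
                default = DEFAULT_CONFIG[key]
                if isinstance(default, bool):
                    values[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(val)
                elif isinstance(default, float):
                    values[key] = float(val)
                else:
                    values[key] = val
            else:
                values[key] = val  # rejected with a named diagnostic below
        return cls(values=values)


def simplify_loadings(
    model: PCAModel,
    drop_tol: float = 0.1,
    merge_tol: float = 0.2,
    n_components: int = 3,
) -> list[dict[str, object]]:
    """Readable per-component loading summary.

    Coefficients below ``drop_tol`` in magnitude are reported as dropped;
    pairs of retained variables whose coefficients agree in sign and whose
    normalized difference ``|a - b| / (|a| + |b|)`` is below ``merge_tol``
    are flagged as merge candidates with their mean coefficient — e.g. the
    two APA durations typically merge into a single "mean APA" term.
    """
    out = []
    for c in range(min(n_components, model.loadings.shape[1])):
        coeffs = model.loadings[:, c]
        kept = {name: float(coeffs[i])
                for i, name in enumerate(model.feature_names)
                if abs(coeffs[i]) >= drop_tol}
        dropped = [name for name in model.feature_names if name not in kept]
        names = list(kept)
        merges = []
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                ca, cb = kept[names[a]], kept[names[b]]
                if ca * cb > 0 and abs(ca - cb) < merge_tol * (abs(ca) + abs(cb)):
                    merges.append({
                        "pair": [names[a], names[b]],
                        "mean_coefficient": (ca + cb) / 2.0,
                    })
        out.append({
            "component": c + 1,
            "kept": kept,
            "dropped": dropped,
            "merge_candidates": merges,
            "single_variable": names[0] if len(names) == 1 else None,
        })
    return out


def realized_overlap(
    features: pd.DataFrame,
    B: int = 2500,
    seed: int = 0,
    level: float = 0.95,
    pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3)),
) -> float:
    """Mean ellipse-membership Jaccard of the two groups' bootstrapped-mean
    clouds over the given PC subspaces (cheap: no mixture fit)."""
    model = fit_pca(features)
    k = max(max(p) for p in pairs)
    scores = project(model, features, k)
    g = features["group"].to_numpy().astype(str)
    labels = sorted(set(g))
    streams = np.random.SeedSequence(seed).spawn(2)
    clouds = [
        bootstrap_means(scores[g == lab], B=B,
                        seed=np.random.default_rng(ss), group=lab)
        for lab, ss in zip(labels, streams)
    ]
    return float(np.mean([
        jaccard_overlap(clouds[0].means[:, [i - 1, j - 1]],
                        clouds[1].means[:, [i - 1, j - 1]], level=level)
        for i, j in pairs
    ]))


def tune_effect_scale(
    make_features,
    target: float = 0.10,
    lo: float = 0.3,
    hi: float = 1.8,
    iters: int = 9,
    B: int = 2500,
    seed: int = 0,
) -> float:
    """Bisect a cohort's group separation so the realized cloud overlap hits
    ``target``.

    ``make_features(scale)`` must return a labelled feature table for a
    given effect scale.  The search works on the decreasing branch of
    J(scale); if even ``hi`` leaves J above target the overlap cannot be
    reduced further for this cohort and ``hi`` is returned.
    """
    if realized_overlap(make_features(hi), B=B, seed=seed) > target:
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if realized_overlap(make_features(mid), B=B, seed=seed) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class SubspaceResult:
    """Per-2-D-subspace outputs: overlap, mixture and confusion."""

    pair: tuple[int, int]
    jaccard: float
    confusion: pd.DataFrame
    per_group_accuracy: dict[str, float]
    gmm_weights: np.ndarray
    gmm_means: np.ndarray
    gmm_covariances: np.ndarray
    gmm_converged: bool


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    config: dict[str, object]
    n_rows: dict[str, int]
    explained_fraction: list[float]
    n_components: int
    simplified_loadings: list[dict[str, object]]
    subspaces: list[SubspaceResult]
    clouds: dict[str, BootstrapCloud]
    pca_model: PCAModel
    version: str = __version__

    def to_dict(self) -> dict[str, object]:
        return {
            "version": self.version,
            "config": self.config,
            "n_rows": self.n_rows,
            "explained_fraction": self.explained_fraction,
            "n_components": self.n_components,
            "simplified_loadings": self.simplified_loadings,
            "subspaces": [
                {
                    "pair": list(s.pair),
                    "jaccard": s.jaccard,
                    "confusion_percent": s.confusion.round(12).to_dict(),
                    "per_group_accuracy": s.per_group_accuracy,
                    "gmm": {
                        "weights": s.gmm_weights.tolist(),
                        "means": s.gmm_means.tolist(),
                        "covariances": s.gmm_covariances.tolist(),
                        "converged": bool(s.gmm_converged),
                    },
                }
                for s in self.subspaces
            ],
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True))
        self.pca_model.to_json(out / "pca_model.json")
        for s in self.subspaces:
            s.confusion.to_csv(out / f"confusion_pc{s.pair[0]}{s.pair[1]}.csv")
        rows = []
        for group, cloud in self.clouds.items():
            df = pd.DataFrame(
                cloud.means,
                columns=[f"PC{c + 1}" for c in range(cloud.means.shape[1])])
            df.insert(0, "replicate", np.arange(cloud.B))
            df.insert(0, "group", group)
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(
            out / "cloud_means.csv", index=False)


def extract_feature_table(
    trials: dict[str, list[TrialRecording]],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Kinetics path: one feature row per trial, labelled by group.

    ``trials`` maps group label -> list of recordings.
    """
    cfg = config or RunConfig()
    rows = []
    for group, recs in trials.items():
        for i, rec in enumerate(recs):
            feats = extract_features(
                rec,
                fc=float(cfg["filter.fc"]),        # type: ignore[arg-type]
                order=int(cfg["filter.order"]),    # type: ignore[arg-type]
                k_sigma=float(cfg["events.k_sigma"]),      # type: ignore[arg-type]
                min_sustain_ms=float(cfg["events.min_sustain_ms"]),  # type: ignore[arg-type]
                baseline_s=float(cfg["events.baseline_s"]),  # type: ignore[arg-type]
            )
            row = {"participant_id": f"{group}_{i + 1:02d}", "group": group}
            row.update(feats.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    features: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the full analysis on a labelled feature table.

    Stages: standardize + PCA on the pooled table; select the number of
    components by cumulative explained variance; project; bootstrap each
    group's mean score vector; per 2-D subspace compute the ellipse-based
    Jaccard overlap, fit the unsupervised mixture to the pooled clouds and
    tabulate the label-aligned confusion matrix.
    """
    cfg = config or RunConfig()
    pairs = cfg.subspace_pairs()

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("validate"):
        if "group" not in features.columns:
            raise ValueError("feature table needs a 'group' column")
        groups = [g for g in GROUPS if g in set(features["group"])]
        if len(groups) < 2:
            groups = sorted(set(features["group"].astype(str)))
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        for g in groups:
            if (features["group"] == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 rows")

    with stage("pca"):
        model = fit_pca(features)
        k_var = model.n_components_for(float(cfg["pca.var_threshold"]))  # type: ignore[arg-type]
        k = max(k_var, max(max(p) for p in pairs))
        scores = project(model, features, k)

    with stage("bootstrap"):
        B = int(cfg["bootstrap.B"])  # type: ignore[arg-type]
        streams = np.random.SeedSequence(cfg.seed).spawn(len(groups) + len(pairs))
        clouds: dict[str, BootstrapCloud] = {}
        for g, ss in zip(groups, streams[: len(groups)]):
            rows = scores[(features["group"] == g).to_numpy()]
            clouds[g] = bootstrap_means(
                rows, B=B, seed=np.random.default_rng(ss), group=g)

    level = float(cfg["ellipse.level"])  # type: ignore[arg-type]
    results: list[SubspaceResult] = []
    for pair, ss in zip(pairs, streams[len(groups):]):
        with stage(f"subspace_pc{pair[0]}{pair[1]}"):
            dims = (pair[0] - 1, pair[1] - 1)
            a = clouds[groups[0]].means[:, list(dims)]
            b = clouds[groups[1]].means[:, list(dims)]
            J = jaccard_overlap(
                a, b, level=level,
                method=str(cfg["jaccard.method"]),
                seed=np.random.default_rng(ss))
            pooled = np.vstack([a, b])
            true = np.array([groups[0]] * B + [groups[1]] * B)
            gmm = fit_gmm(
                pooled,
                K=int(cfg["gmm.K"]),            # type: ignore[arg-type]
                seed=np.random.default_rng(ss),
                tol=float(cfg["gmm.tol"]),      # type: ignore[arg-type]
                max_iter=int(cfg["gmm.max_iter"]),  # type: ignore[arg-type]
                n_init=int(cfg["gmm.n_init"]),      # type: ignore[arg-type]
                reg_floor=float(cfg["gmm.reg_floor"]),  # type: ignore[arg-type]
            )
            labels, _ = classify(gmm, pooled)
            cm = align_and_confuse(true, labels)
            results.append(SubspaceResult(
                pair=pair,
                jaccard=J,
                confusion=cm.to_frame(),
                per_group_accuracy=cm.per_group_accuracy,
                gmm_weights=gmm.weights,
                gmm_means=gmm.means,
                gmm_covariances=gmm.covariances,
                gmm_converged=gmm.converged,
            ))

    with stage("report"):
        report = RunReport(
            config=dict(cfg.values),
            n_rows={g: int((features["group"] == g).sum()) for g in groups},
            explained_fraction=model.explained_fraction.tolist(),
            n_components=k,
            simplified_loadings=simplify_loadings(
                model,
                drop_tol=float(cfg["simplify.drop_tol"]),   # type: ignore[arg-type]
                merge_tol=float(cfg["simplify.merge_tol"]),  # type: ignore[arg-type]
                n_components=k,
            ),
            subspaces=results,
            clouds=clouds,
            pca_model=model,
        )
        if out_dir is not None:
            report.write(out_dir)
    return report
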