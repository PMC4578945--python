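"""End-to-end orchestration: transform → decompose → BD/LCBD → strata →
trajectories → space–time tests → MRT / chronological shifts → indicator
species, with all artifacts written as CSV/JSON plus one summary JSON.

Every stochastic stage draws its own seed deterministically from the run
seed, and the summary records which seed each stage used, so a rerun with
the same inputs and seed reproduces the summary byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityTable, apply_transform, read_community
from .dissimilarity import decompose_matrix
from .betadiv import BetaDiversity
from .strata import summarize_strata
from .trajectories import fit_linear, fit_logistic, fit_quadratic, select_model, stepwise_regression
from .spacetime import embed_for_tests, rda, two_way_crossed_anova
from .mrt import chronological_split, mrt_fit
from .indicators import indval_test, select_shift_species

log = logging.getLogger("betashift")

ALL_STAGES = ("lcbd", "strata", "trajectories", "spacetime", "mrt", "shift", "figures")


@dataclass
class RunConfig:
    community: str | None = None
    meta: str | None = None
    out_dir: str = "results"
    transform: str = "sqrt"
    n_perm: int = 999
    indval_n_perm: int = 4999   # Holm over ~227 species needs p resolution < alpha/m
    alpha: float = 0.05
    seed: int = 0
    frequency_floor: float = 0.001
    max_leaves: int = 4
    stages: tuple = field(default_factory=lambda: ALL_STAGES)

    def __post_init__(self):
        if self.n_perm < 99:
            raise ValueError("n_perm must be ≥ 99 for reported p-values")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _table_hash(table: CommunityTable) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.matrix()).tobytes())
    h.update(",".join(map(str, table.obs_ids)).encode())
    return h.hexdigest()[:16]


def _fit_trajectories(table: CommunityTable) -> pd.DataFrame:
    """Per-site model selection for coral cover, √total biomass and richness."""
    raw = table.matrix()
    meta = table.meta
    responses = {
        "biomass_sqrt": np.sqrt(raw.sum(axis=1)),
        "richness": (raw > 0).sum(axis=1).astype(float),
    }
    if "coral_cover" in meta.columns:
        responses["coral"] = meta["coral_cover"].to_numpy(dtype=float)
    rows = []
    for site, grp in meta.groupby("site", sort=True):
        idx = meta.index.get_indexer(grp.index)
        t = grp["time"].to_numpy(dtype=float)
        for name, y_all in responses.items():
            y = y_all[idx]
            fits = [fit_linear(t, y), fit_quadratic(t, y)]
            try:
                fits.append(fit_logistic(t, y))
            except ValueError:
                pass
            best = select_model(fits)
            rows.append(
                {
                    "site": site,
                    "response": name,
                    "model": best.kind,
                    "r2": best.r2,
                    "aic": best.aic,
                    "decline_pct": best.decline_pct,
                    "vertex_time": best.vertex_time,
                    "inflection_T": best.params.get("T"),
                    "params": json.dumps(
                        {k: v for k, v in best.params.items() if isinstance(v, (int, float))}
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, table: CommunityTable | None = None) -> dict:
    """Execute the configured stages and write artifacts under ``out_dir``.

    ``table`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.community`` / ``config.meta`` are read.  Returns the
    in-memory report bundle; the summary is also written to ``summary.json``.
    Any stage failure raises with the stage name; artifacts of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        if config.community is None or config.meta is None:
            raise ValueError("either a table or community/meta paths are required")
        table = read_community(config.community, config.meta)
    st = apply_transform(table, config.transform)
    bundle: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "input_hash": _table_hash(table),
        "n_obs": table.n_obs,
        "n_species": table.n_species,
        "stages": {},
    }
    stage_order = [s for s in ALL_STAGES if s in config.stages and s != "figures"]

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log.error("stage=%s status=failed error=%r", name, exc)
            _write_summary(bundle, out)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info(
            "stage=%s status=ok wall_s=%.2f input=%s",
            name, time.perf_counter() - t0, bundle["input_hash"],
        )
        bundle["stages"][name] = result

    # decomposition underlies almost every stage
    dec = decompose_matrix(st)
    for frame_name, frame in dec.to_frames().items():
        frame.to_csv(out / f"{frame_name}.csv")
    dec.to_long().to_csv(out / "pairs.csv", index=False)

    if "lcbd" in stage_order:
        def _lcbd():
            seed = _stage_seed(config.seed, "lcbd")
            bd = BetaDiversity(n_perm=config.n_perm, seed=seed).fit(st)
            bd.result_().to_frame(config.alpha).to_csv(out / "lcbd.csv")
            return {
                "SS_total": bd.ss_total_,
                "BD_total": bd.bd_total_,
                "n_perm": config.n_perm,
                "seed": seed,
                "n_significant": int((bd.p_values_ <= config.alpha).sum()),
            }
        run_stage("lcbd", _lcbd)

    if "strata" in stage_order:
        def _strata():
            frames = [summarize_strata(st, dec, by="site"),
                      summarize_strata(st, dec, by="time")]
            summ = pd.concat(frames, ignore_index=True)
            summ.to_csv(out / "group_summaries.csv", index=False)
            by_scope = summ.groupby("scope")[["mean_sim", "mean_repl", "mean_diff",
                                              "frac_repl", "frac_diff"]].mean()
            return {s: by_scope.loc[s].to_dict() for s in by_scope.index}
        run_stage("strata", _strata)

    if "trajectories" in stage_order:
        def _traj():
            traj = _fit_trajectories(table)
            traj.to_csv(out / "trajectories.csv", index=False)
            raw = table.matrix()
            season = table.meta["season"] if "season" in table.meta.columns else None
            stepwise = {}
            for name, y in (
                ("richness", (raw > 0).sum(axis=1).astype(float)),
                ("biomass_sqrt", np.sqrt(raw.sum(axis=1))),
            ):
                sw = stepwise_regression(
                    y, table.meta["time"].to_numpy(dtype=float),
                    table.meta["site"].to_numpy(), season,
                )
                stepwise[name] = {
                    "retained": sw.retained,
                    "r2": sw.r2,
                    "df": [sw.df_model, sw.df_resid],
                    "F": sw.f_full,
                    "p": sw.p_full,
                    "anova": sw.anova.to_dict("records"),
                }
            (out / "stepwise.json").write_text(json.dumps(stepwise, indent=2))
            summary = {}
            for name in traj["response"].unique():
                sub = traj[traj["response"] == name]
                summary[name] = {
                    "models": sub["model"].value_counts().to_dict(),
                    "mean_r2": float(sub["r2"].mean()),
                }
                if name == "coral":
                    summary[name]["mean_decline_pct"] = float(sub["decline_pct"].dropna().mean())
                    summary[name]["median_inflection"] = float(sub["inflection_T"].dropna().median())
            return summary
        run_stage("trajectories", _traj)

    coords = None
    if {"spacetime", "mrt"} & set(stage_order):
        coords = embed_for_tests(dec)

    if "spacetime" in stage_order:
        def _spacetime():
            seed = _stage_seed(config.seed, "spacetime")
            res = two_way_crossed_anova(
                coords, table.meta["site"].to_numpy(), table.meta["time"].to_numpy(),
                n_perm=config.n_perm, seed=seed,
            )
            payload = {
                "r2": res.r2,
                "n_perm": config.n_perm,
                "seed": seed,
                "terms": res.terms.to_dict("records"),
            }
            (out / "spacetime.json").write_text(json.dumps(payload, indent=2))
            return payload
        run_stage("spacetime", _spacetime)

    if "mrt" in stage_order:
        def _mrt():
            seed = _stage_seed(config.seed, "mrt")
            preds = table.meta[["site", "time"]].reset_index(drop=True)
            tree = mrt_fit(coords, preds, max_leaves=config.max_leaves,
                           alpha=config.alpha, n_perm=config.n_perm, seed=seed)
            (out / "mrt.json").write_text(json.dumps(tree.to_dict(), indent=2))
            labeled = table.meta.copy()
            labeled["mrt_group"] = tree.labels
            labeled.rename_axis("obs_id").to_csv(out / "meta_with_groups.csv")
            return {"n_leaves": tree.n_leaves, "r2_path": tree.r2_path, "seed": seed}
        run_stage("mrt", _mrt)

    if "shift" in stage_order:
        def _shift():
            seed = _stage_seed(config.seed, "shift")
            X_sqrt = st.matrix()
            raw_vals = table.values
            shift_rows, species_frames = [], []
            for site, grp in table.meta.groupby("site", sort=True):
                idx = table.meta.index.get_indexer(grp.index)
                cs = chronological_split(
                    X_sqrt[idx], grp["time"].to_numpy(dtype=float),
                    n_perm=config.n_perm, seed=seed,
                )
                shift_rows.append(
                    {"site": site, "boundary": cs.boundary, "r2": cs.r2, "p": cs.p}
                )
                if cs.p is not None and cs.p > config.alpha:
                    continue
                iv = indval_test(raw_vals.iloc[idx], cs.labels,
                                 n_perm=config.indval_n_perm, seed=seed)
                scores = rda(X_sqrt[idx], cs.labels)
                sel = select_shift_species(
                    iv, scores.species_scores, scores.species_share,
                    alpha=config.alpha, frequency_floor=config.frequency_floor,
                )
                sel.insert(0, "site", site)
                species_frames.append(sel)
            shifts = pd.DataFrame(shift_rows)
            shifts.to_csv(out / "shifts.csv", index=False)
            species = (
                pd.concat(species_frames, ignore_index=True)
                if species_frames else pd.DataFrame()
            )
            species.to_csv(out / "shift_species.csv", index=False)
            return {
                "seed": seed,
                "n_sites_significant": int((shifts["p"] <= config.alpha).sum()),
                "r2_range": [float(shifts["r2"].min()), float(shifts["r2"].max())],
                "n_indicator_selections": int(len(species)),
                "indval_n_perm": config.indval_n_perm,
            }
        run_stage("shift", _shift)

    if "figures" in config.stages:
        from .figures import render_figures
        def _figures():
            return render_figures(bundle, table, dec, out)
        run_stage("figures", _figures)

    _write_summary(bundle, out)
    return bundle


def _write_summary(bundle: dict, out: Path) -> None:
    (out / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
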