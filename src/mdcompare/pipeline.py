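"""Configuration-driven orchestration of the comparative analysis.

A run takes a reference state and one or more modified states, each a
set of replicate trajectories, and sequences the stages: flexibility
(RMSF, secondary structure), hydrogen-bond occupancy, binding-energy
summaries with exact Mann-Whitney tests, ensemble-ML residue importance
and the category classification.  All stage outputs are CSV/JSON with
headers and units, every random step is seeded from the config, and an
identical config over identical inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import energetics, geometry, hbond, ml_importance, model_io, stats

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All numeric conventions of a comparative run, with field defaults
    matching the analysis conventions this pipeline standardises:
    final-window sampling, 500 energy frames, 5000 ML frames, 250
    water-bridge frames, 1250 secondary-structure frames, 3.5 A / 30 deg
    H-bond criteria, 10 % occupancy filter, 0.8 importance, 2 kJ/mol
    energy and 1 A / 3 A RMSF thresholds."""

    states: dict[str, list[str]] = field(default_factory=dict)
    reference_state: str | None = None  # default: first key of states
    parameter_table: str | None = None
    domain_map: str | None = None
    chain_a: str = "A"
    chain_b: str = "B"
    window_last_fraction: float = 5.0 / 6.0
    n_energy_frames: int = 500
    n_ml_frames: int = 5000
    n_bridge_frames: int = 250
    n_ss_frames: int = 1250
    hbond_criteria: hbond.HBondCriteria = field(default_factory=hbond.HBondCriteria)
    occupancy_min_pct: float = 10.0
    importance_threshold: float = 0.8
    ddg_threshold_kj: float = 2.0
    ml_iterations: int = 20
    seed: int = 0
    test_directions: dict[str, str] = field(default_factory=dict)
    frame_spacing_ns: float = model_io.DEFAULT_FRAME_SPACING_NS

    def validate(self) -> None:
        if len(self.states) < 2:
            raise ConfigError("need a reference and at least one modified state")
        for label, paths in self.states.items():
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"state {label}: missing trajectory {p}")
        if self.parameter_table and not Path(self.parameter_table).exists():
            raise ConfigError(f"missing parameter table {self.parameter_table}")
        if self.domain_map and not Path(self.domain_map).exists():
            raise ConfigError(f"missing domain map {self.domain_map}")
        for thr in (self.occupancy_min_pct, self.importance_threshold,
                    self.ddg_threshold_kj):
            if thr <= 0:
                raise ConfigError("thresholds must be positive")


def load_config(path) -> RunConfig:
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    crit = cfg.pop("hbond_criteria", None)
    rc = RunConfig(**{k: v for k, v in cfg.items() if k in RunConfig.__dataclass_fields__})
    if crit:
        rc.hbond_criteria = hbond.HBondCriteria(**crit)
    return rc


@dataclass
class RunReport:
    outdir: Path
    manifest: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def add(self, key: str, path: Path, note: str = "") -> None:
        self.manifest[key] = str(path)
        self.log.append(f"wrote {key}: {path} {note}".rstrip())

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n")
        (self.outdir / "run.log").write_text("\n".join(self.log) + "\n")


def _load_states(cfg: RunConfig) -> dict[str, model_io.StateEnsemble]:
    ensembles: dict[str, model_io.StateEnsemble] = {}
    topology = None
    for label, paths in cfg.states.items():
        replicates = []
        for p in paths:
            t = model_io.read_trajectory(p, topology=topology,
                                         frame_spacing_ns=cfg.frame_spacing_ns)
            if topology is None:
                topology = t.topology
                if cfg.parameter_table:
                    model_io.apply_parameters(
                        topology, model_io.read_parameter_table(cfg.parameter_table))
            replicates.append(model_io.Trajectory(topology, t.coords, t.times))
        ensembles[label] = model_io.StateEnsemble(state_label=label,
                                                  replicates=replicates)
    return ensembles


def _window(traj: model_io.Trajectory, cfg: RunConfig,
            n_samples: int) -> model_io.Trajectory:
    t0 = traj.times[-1] - cfg.window_last_fraction * (traj.times[-1] - traj.times[0])
    t0 = max(t0, traj.times[0])
    avail = int(np.sum((traj.times >= t0)))
    return model_io.window_frames(traj, (t0, traj.times[-1]),
                                  min(n_samples, avail))


def run_pipeline(cfg: RunConfig, outdir) -> RunReport:
    """Execute geometry -> hbond -> energetics -> stats -> ML -> categories.

    Any stage failure aborts with the stage name; outputs written so far
    are kept under a ``failed`` marker file.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)
    report.log.append(f"seed={cfg.seed}")
    report.log.append(f"thresholds: occupancy>={cfg.occupancy_min_pct}% "
                      f"importance>{cfg.importance_threshold} "
                      f"|ddG|>={cfg.ddg_threshold_kj} kJ/mol "
                      f"|dRMSF|>={geometry.ORDERED_DELTA_RMSF_A}/"
                      f"{geometry.DISORDERED_DELTA_RMSF_A} A")
    try:
        _run_stages(cfg, outdir, report)
    except Exception as exc:
        (outdir / "failed").write_text(str(exc) + "\n")
        report.write()
        if isinstance(exc, StageError):
            raise
        raise StageError("pipeline", str(exc)) from exc
    report.write()
    return report


def _run_stages(cfg: RunConfig, outdir: Path, report: RunReport) -> None:
    ensembles = _load_states(cfg)
    labels = list(ensembles)
    ref_label = cfg.reference_state or labels[0]
    mod_labels = [l for l in labels if l != ref_label]
    top = ensembles[ref_label].topology

    # ---- geometry: per-state RMSF on concatenated final windows ----
    stage = "geometry"
    try:
        reference = ensembles[ref_label].replicates[0].coords[0]
        ca_sel = top.atom_indices(name="CA")
        profiles = {}
        for label, ens in ensembles.items():
            concat = model_io.concatenate(
                [_window(r, cfg, r.n_frames) for r in ens.replicates])
            profiles[label] = geometry.rmsf_profile(concat, reference,
                                                    fit_selection=ca_sel,
                                                    reference_id=ref_label)
            profiles[label].as_frame().to_csv(outdir / f"rmsf_{label}.csv",
                                              index=False)
            report.add(f"rmsf_{label}", outdir / f"rmsf_{label}.csv")
        delta_profiles = {}
        for label in mod_labels:
            prof, regions = geometry.flag_flexible_regions(
                profiles[ref_label], profiles[label])
            delta_profiles[label] = prof
            prof.as_frame().to_csv(outdir / f"delta_rmsf_{label}.csv", index=False)
            with open(outdir / f"flex_regions_{label}.tsv", "w") as fh:
                fh.write("start_pos\tend_pos\tmax_abs_delta_A\n")
                for s, e, m in regions:
                    fh.write(f"{s}\t{e}\t{m:.3f}\n")
            report.add(f"delta_rmsf_{label}", outdir / f"delta_rmsf_{label}.csv")
            report.add(f"flex_regions_{label}", outdir / f"flex_regions_{label}.tsv")

        for label, ens in ensembles.items():
            concat = model_io.concatenate(
                [_window(r, cfg, r.n_frames) for r in ens.replicates])
            n = min(cfg.n_ss_frames, concat.n_frames)
            idx = np.round(np.linspace(0, concat.n_frames - 1, n)).astype(int)
            ssp = geometry.ss_fractions(concat.subset(np.unique(idx)))
            ssp.as_frame().to_csv(outdir / f"ss_fractions_{label}.csv", index=False)
            report.add(f"ss_fractions_{label}", outdir / f"ss_fractions_{label}.csv",
                       f"({n} frames)")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- hbond occupancy per replicate, filtered across states ----
    stage = "hbond"
    try:
        tables = []
        for label, ens in ensembles.items():
            for k, rep in enumerate(ens.replicates):
                w = _window(rep, cfg, rep.n_frames)
                tables.append(hbond.occupancy(w, cfg.hbond_criteria,
                                              column=f"{label}_{k + 1}"))
        filtered = hbond.filter_occupancy(tables, cfg.occupancy_min_pct)
        filtered.as_frame().to_csv(outdir / "hbond_occupancy.csv")
        report.add("hbond_occupancy", outdir / "hbond_occupancy.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- energetics + stats ----
    stage = "energetics"
    has_params = all(a.partial_charge is not None for a in top.atoms)
    ddg_by_state: dict[str, dict[str, float]] = {}
    if has_params:
        try:
            ga = top.atom_indices(chain_id=cfg.chain_a)
            gb = top.atom_indices(chain_id=cfg.chain_b)
            values_by_state: dict[str, list[float]] = {}
            for label, ens in ensembles.items():
                reps = []
                res_means: dict[str, list[float]] = {}
                for rep in ens.replicates:
                    sample = _window(rep, cfg, cfg.n_energy_frames)
                    _, summ = energetics.binding_energy(sample, ga, gb)
                    reps.append(summ.mean)
                    dec = energetics.per_residue_decomposition(
                        sample, ga, gb, state_label=label)
                    for rlabel, comp in dec.components.items():
                        res_means.setdefault(rlabel, []).append(comp.g_total)
                values_by_state[label] = reps
                ddg_by_state[label] = {k: float(np.mean(v))
                                       for k, v in res_means.items()}
            pairings = [(ref_label, m) for m in mod_labels]
            summaries = energetics.summarize_bfe(values_by_state, pairings,
                                                 per_residue=ddg_by_state)
            rows = []
            for s in summaries:
                direction = cfg.test_directions.get(s.state_b, "less")
                test = stats.mann_whitney_exact(values_by_state[s.state_a],
                                                values_by_state[s.state_b],
                                                alternative=direction)
                rows.append({
                    "reference": s.state_a, "modified": s.state_b,
                    "mean_ref": s.summary_a.rounded_mean,
                    "sd_ref": round(s.summary_a.sd, 1),
                    "mean_mod": s.summary_b.rounded_mean,
                    "sd_mod": round(s.summary_b.sd, 1),
                    "delta_rounded": s.delta_rounded,
                    "delta_raw": s.delta_raw,
                    "U": test.U, "p_one_tailed": test.p_rounded,
                    "direction": direction, "method": test.method,
                })
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "bfe_summary.csv", index=False)
            report.add("bfe_summary", outdir / "bfe_summary.csv")
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    else:
        report.log.append("energetics skipped: no charges/LJ parameters; "
                          "supply parameter_table to enable")

    # ---- ensemble ML importance + categories ----
    stage = "ml_importance"
    try:
        interfaces = _resolve_interfaces(cfg, top, report)
        for label in mod_labels:
            frames = []
            for iid, (res_a, res_b) in interfaces.items():
                matrix = ml_importance.extract_pair_features(
                    ensembles[ref_label], ensembles[label], res_a, res_b,
                    frames_per_replicate=cfg.n_ml_frames, interface_id=iid)
                imp = ml_importance.aggregate_importance(
                    matrix, rng_seed=cfg.seed, n_iterations=cfg.ml_iterations)
                df = imp.as_frame(top)
                df.insert(0, "interface", iid)
                frames.append((imp, df))
            import pandas as pd

            pd.concat([df for _, df in frames]).to_csv(
                outdir / f"importance_{label}.csv", index=False)
            imp = frames[0][0] if len(frames) == 1 else _merge_importance(frames)
            report.add(f"importance_{label}", outdir / f"importance_{label}.csv")
            ddg = {}
            if ddg_by_state:
                ref_map = ddg_by_state[ref_label]
                mod_map = ddg_by_state[label]
                for rid in imp.residues:
                    rl = top.residue_label(rid)
                    if rl in ref_map and rl in mod_map:
                        ddg[rid] = mod_map[rl] - ref_map[rl]
            cats = ml_importance.classify_categories(
                imp, ddg, delta_profiles.get(label),
                importance_threshold=cfg.importance_threshold,
                ddg_threshold=cfg.ddg_threshold_kj)
            cats.as_frame(top).to_csv(outdir / f"categories_{label}.csv",
                                      index=False)
            report.add(f"categories_{label}", outdir / f"categories_{label}.csv")
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc


def _resolve_interfaces(cfg: RunConfig, top, report: RunReport) -> dict:
    """Interface id -> (internal residues side A, side B).

    With a configured domain map, every numbered interface is analysed
    separately (importance normalisation is per interface); otherwise the
    whole chain A / chain B split forms a single interface 1.
    """
    if not cfg.domain_map:
        res_a = [r for r, _, c in top.residues if c == cfg.chain_a]
        res_b = [r for r, _, c in top.residues if c == cfg.chain_b]
        return {1: (res_a, res_b)}
    dm = model_io.load_domain_map(cfg.domain_map)
    dm.validate_against(top)
    by_key = {}
    for a in top.atoms:
        by_key.setdefault((a.chain_id, a.res_seq), a.residue_index)
    out = {}
    for iid, (da, db) in sorted(dm.interfaces.items()):
        chain_a, resseq_a = dm.domain_residues(da)
        chain_b, resseq_b = dm.domain_residues(db)
        out[iid] = ([by_key[(chain_a, r)] for r in resseq_a],
                    [by_key[(chain_b, r)] for r in resseq_b])
    report.log.append(f"ml interfaces: {sorted(out)}")
    return out


def _merge_importance(frames):
    """Union of per-interface importance tables (max score per residue)."""
    all_res = sorted({r for imp, _ in frames for r in imp.residues})
    idx = {r: k for k, r in enumerate(all_res)}
    models = list(frames[0][0].importance)
    merged = {m: np.zeros(len(all_res)) for m in models}
    for imp, _ in frames:
        for m in models:
            for r, v in zip(imp.residues, imp.importance[m]):
                merged[m][idx[r]] = max(merged[m][idx[r]], v)
    return ml_importance.ImportanceTable(
        residues=all_res, importance=merged,
        n_iterations=frames[0][0].n_iterations)


# ---------------------------------------------------------------------------
# Printed-table reproduction
# ---------------------------------------------------------------------------

def reproduce_tables(table, pairings: list[tuple[str, str, str]] | None = None):
    """Summary statistics and exact Mann-Whitney tests for replicate tables.

    ``table`` is a CSV path or DataFrame whose columns are states and
    rows replicate values (an optional ``replicate`` column is ignored).
    ``pairings`` lists (reference, other, alternative) comparisons;
    default: every non-first column against the first, plus consecutive
    non-reference pairs, with direction inferred from the observed means
    (the configured direction should be supplied for hypothesis-driven
    use).  Returns (summary DataFrame, tests DataFrame).
    """
    import pandas as pd

    if not isinstance(table, pd.DataFrame):
        try:
            df = pd.read_csv(table)
        except ValueError as exc:
            raise ConfigError(f"cannot parse replicate table: {exc}") from exc
    else:
        df = table.copy()
    if "replicate" in df.columns:
        df = df.drop(columns=["replicate"])
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.values)[0][0])
            raise ConfigError(
                f"non-numeric cell at column {col!r}, row {row + 1}: "
                f"{df[col].iloc[row]!r}")
    df = df.astype(float)
    states = list(df.columns)
    if len(states) < 2 or len(df) < 2:
        raise ConfigError("need >= 2 state columns of >= 2 replicate values")

    summaries = {s: stats.replicate_summary(df[s].values) for s in states}
    summary_rows = [{"state": s, "mean": round(summaries[s].mean, 1),
                     "sd": round(summaries[s].sd, 1),
                     "n": summaries[s].n} for s in states]

    if pairings is None:
        pairings = []
        ref = states[0]
        for other in states[1:]:
            alt = "greater" if summaries[other].mean > summaries[ref].mean else "less"
            pairings.append((ref, other, alt))
        for a, b in zip(states[1:], states[2:]):
            alt = "greater" if summaries[b].mean > summaries[a].mean else "less"
            pairings.append((a, b, alt))
    test_rows = []
    for ref, other, alt in pairings:
        t = stats.mann_whitney_exact(df[ref].values, df[other].values,
                                     alternative=alt)
        test_rows.append({
            "reference": ref, "state": other,
            "delta_rounded": stats.state_delta(summaries[ref], summaries[other],
                                               "rounded"),
            "delta_raw": stats.state_delta(summaries[ref], summaries[other],
                                           "raw"),
            "U": t.U, "p_one_tailed": t.p_rounded,
            "p_full_precision": t.p_one_tailed,
            "alternative": alt, "method": t.method,
        })
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def packaged_table(name: str):
    """Load one of the shipped replicate tables.

    ``protein_protein`` -- per-replicate protein-protein binding free
    energies (kJ/mol) for the three states; ``ligand`` -- per-replicate
    ligand binding free energies; ``residue_delta`` -- selected published
    per-residue mean BFE differences (kJ/mol).
    """
    import pandas as pd
    from importlib.resources import files

    fname = {"protein_protein": "protein_protein_bfe.csv",
             "ligand": "ligand_bfe.csv",
             "residue_delta": "residue_delta_bfe.csv"}[name]
    with (files("mdcompare.data") / fname).open() as fh:
        return pd.read_csv(fh)
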