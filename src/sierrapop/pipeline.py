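"""End-to-end workflow orchestration.

Runs the full analysis in its canonical order — temporal pooling, diversity,
pairwise Φ_ST with Bonferroni correction, hierarchical AMOVA, Slatkin/UPGMA
population tree, isolation by distance, haplotype NJ tree with bootstrap,
mismatch expansion fits with Fu's Fs, and (optionally) pairwise
isolation-with-migration MCMC — from one structured YAML config.  Every
output table carries the config hash and seed; a failing stage is recorded
and its dependents skipped, leaving a resumable report of what completed.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demography, diversity, im, phylogeny, sequences, simulate, structure

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Structured pipeline configuration (see ``RunConfig.from_yaml``)."""

    outdir: str
    fasta: str | None = None
    labels: str | None = None
    simulate_study_like: bool = False
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 999
    gamma_alpha: float = 0.4
    n_boot: int = 200
    fu_sims: int = 500
    bootstrap_B: int = 200
    tree_max_taxa: int = 60          # haplotype representatives in the NJ tree
    outgroup: str | None = None
    temporal_replicates: dict[str, list[str]] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    geo_tsv: str | None = None
    ibd_exclude: str | None = None
    run_im: bool = False
    im_pairs: list[list[str]] = field(default_factory=list)
    im_cycles: int = 100_000
    im_burnin: int = 20_000
    rate_per_site_per_year: float = 3.6e-8
    generation_years: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate_study_like:
            if not self.fasta or not self.labels:
                raise ConfigError("either simulate_study_like or fasta+labels "
                                  "must be given")
            for p in (self.fasta, self.labels):
                if not Path(p).exists():
                    raise ConfigError(f"input file missing: {p}")
        if self.geo_tsv and not Path(self.geo_tsv).exists():
            raise ConfigError(f"geo distance file missing: {self.geo_tsv}")

    def digest(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a status dict (also saved as JSON)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, dict] = {}
    rm = demography.RateModel(rate_per_site_per_year=cfg.rate_per_site_per_year,
                              generation_years=cfg.generation_years)

    def log(stage: str, msg: str) -> None:
        line = (f"{time.strftime('%Y-%m-%dT%H:%M:%S')} stage={stage} "
                f"config={cfg.digest()} seed={cfg.seed} {msg}")
        print(line)
        with open(out / "pipeline.log", "a") as fh:
            fh.write(line + "\n")

    def run_stage(name: str, fn, *, requires: tuple[str, ...] = ()):
        for r in requires:
            if status.get(r, {}).get("state") != "ok":
                status[name] = {"state": "skipped",
                                "reason": f"dependency {r} not ok"}
                log(name, "action=skip")
                return None
        try:
            t0 = time.time()
            result = fn()
            status[name] = {"state": "ok", "seconds": round(time.time() - t0, 2)}
            log(name, f"action=done seconds={status[name]['seconds']}")
            return result
        except Exception as err:                     # noqa: BLE001
            status[name] = {"state": "failed", "error": str(err)}
            log(name, f"action=fail error={err!r}")
            traceback.print_exc()
            return None

    # ---- load / simulate --------------------------------------------------
    def stage_input():
        if cfg.simulate_study_like:
            aln, truth = simulate.make_study_like_dataset(cfg.seed, outdir=out)
            return aln
        return sequences.read_alignment(cfg.fasta, cfg.labels)

    aln = run_stage("input", stage_input)
    if aln is None:
        (out / "status.json").write_text(json.dumps(status, indent=1))
        return status

    pops = {p: [r.id for r in aln.records if r.population == p]
            for p in aln.populations}

    def stage_distances():
        return diversity.tn93_distance_matrix(aln, cfg.gamma_alpha)

    dm = run_stage("distances", stage_distances)

    # ---- temporal pooling -------------------------------------------------
    def stage_pooling():
        rows = []
        for location, reps in cfg.temporal_replicates.items():
            plan = structure.pool_temporal_samples(
                dm, pops, reps, alpha=cfg.alpha, n_perm=cfg.n_perm,
                seed=cfg.seed)
            rows.append({"location": location,
                         "pooled": ",".join(plan.pooled),
                         "separate": ",".join(plan.separate),
                         "flagged": ",".join(plan.flagged)})
        df = pd.DataFrame(rows)
        if len(df):
            _write(df, out / "pooling.tsv", cfg)
        return df

    if cfg.temporal_replicates:
        run_stage("pooling", stage_pooling, requires=("distances",))

    # ---- diversity --------------------------------------------------------
    def stage_diversity():
        df = diversity.diversity_table(aln)
        _write(df, out / "diversity.tsv", cfg)
        return df

    run_stage("diversity", stage_diversity)

    # ---- pairwise Phi_ST --------------------------------------------------
    def stage_phist():
        df = structure.pairwise_phi_matrix(dm, pops, n_perm=cfg.n_perm,
                                           seed=cfg.seed)
        thr = structure.bonferroni(df.p.tolist(), cfg.alpha)["threshold"]
        df["stars"] = df.p.map(structure.significance_stars)
        df["bonferroni_significant"] = df.p < thr
        _write(df, out / "phi_st.tsv", cfg)
        return df

    phi_df = run_stage("phi_st", stage_phist, requires=("distances",))

    # ---- AMOVA ------------------------------------------------------------
    def stage_amova():
        res = structure.hierarchical_amova(dm, pops, cfg.groups,
                                           n_perm=min(cfg.n_perm, 999),
                                           seed=cfg.seed)
        df = pd.DataFrame([{
            "phi_ct": res.phi_ct, "phi_sc": res.phi_sc, "phi_st": res.phi_st,
            "p_ct": res.p_ct, "p_sc": res.p_sc, "p_st": res.p_st,
            "var_among_groups": res.var_among_groups,
            "var_among_pops": res.var_among_pops,
            "var_within": res.var_within}])
        _write(df, out / "amova.tsv", cfg)
        return res

    if cfg.groups:
        run_stage("amova", stage_amova, requires=("distances",))

    # ---- Slatkin UPGMA ----------------------------------------------------
    def stage_upgma():
        D, newick = structure.slatkin_upgma(phi_df)
        (out / "upgma_slatkin.nwk").write_text(newick + "\n")
        return newick

    run_stage("upgma", stage_upgma, requires=("phi_st",))

    # ---- IBD --------------------------------------------------------------
    def stage_ibd():
        geo = pd.read_csv(cfg.geo_tsv, sep="\t", index_col=0)
        labels = sorted(set(phi_df.pop_a) | set(phi_df.pop_b))
        geo = geo.loc[labels, labels].to_numpy(dtype=float)
        res = structure.mantel_ibd(phi_df, geo, n_perm=cfg.n_perm,
                                   seed=cfg.seed, exclude=cfg.ibd_exclude)
        df = pd.DataFrame([{"r": res.r, "r2": res.r2, "p": res.p,
                            "excluded_pairs": len(res.excluded_pairs)}])
        _write(df, out / "ibd.tsv", cfg)
        return res

    if cfg.geo_tsv:
        run_stage("ibd", stage_ibd, requires=("phi_st",))

    # ---- haplotype NJ tree ------------------------------------------------
    def stage_tree():
        spec = sequences.collapse_haplotypes(aln)
        # most frequent haplotypes first; cap for tractable bootstrapping
        ranked = sorted(spec.members.values(), key=len, reverse=True)
        reps = [members[0] for members in ranked[:cfg.tree_max_taxa]]
        keep = set(reps)
        if cfg.outgroup:
            keep.add(cfg.outgroup)
        sub = sequences.Alignment(records=[
            sequences.Record(r.id, r.population, r.year, r.seq)
            for r in aln.records if r.id in keep])
        st = phylogeny.bootstrap_support(sub, B=cfg.bootstrap_B,
                                         seed=cfg.seed,
                                         outgroup=cfg.outgroup,
                                         gamma_alpha=cfg.gamma_alpha)
        (out / "nj_haplotypes.nwk").write_text(st.newick() + "\n")
        return st

    run_stage("nj_tree", stage_tree)

    # ---- mismatch + Fu's Fs ----------------------------------------------
    def stage_demography():
        rows = []
        for i, pop in enumerate(aln.populations):
            hist = demography.mismatch_histogram(aln, pop)
            dfit = demography.fit_demographic_expansion(
                hist, n_boot=cfg.n_boot, seed=cfg.seed + i, rm=rm)
            sfit = demography.fit_spatial_expansion(
                hist, n_boot=cfg.n_boot, seed=cfg.seed + i, rm=rm)
            fs = demography.fu_fs(aln, pop, n_sim=cfg.fu_sims,
                                  seed=cfg.seed + i)
            t_ky = demography.tau_to_time(dfit.tau, rm)[2]
            rows.append({
                "population": pop,
                "tau_dem": round(dfit.tau, 2), "T_ky_dem": round(t_ky, 1),
                "T_ky_dem_ci": ("%.1f-%.1f" % dfit.time_ci95_ky
                                if dfit.time_ci95_ky else ""),
                "theta0": round(dfit.theta0, 2),
                "N0": round(demography.theta_to_N(dfit.theta0, rm)),
                "theta1": round(dfit.theta1, 1),
                "N1": round(demography.theta_to_N(dfit.theta1, rm)),
                "ssd_dem": round(dfit.ssd, 5), "p_ssd_dem": dfit.p_ssd,
                "tau_sp": round(sfit.tau, 2),
                "T_ky_sp": round(demography.tau_to_time(sfit.tau, rm)[2], 1),
                "theta_sp": round(sfit.theta, 2),
                "N_sp": round(demography.theta_to_N(sfit.theta, rm)),
                "M_sp": round(sfit.M, 1), "m_sp": sfit.m,
                "ssd_sp": round(sfit.ssd, 5), "p_ssd_sp": sfit.p_ssd,
                "fu_fs": round(fs.fs, 2), "fu_p": fs.p,
                "flags": ";".join(dfit.boundary_flags + sfit.boundary_flags),
            })
            pd.DataFrame({"differences": np.arange(len(hist.counts)),
                          "pairs": hist.counts}).to_csv(
                out / f"mismatch_{pop}.tsv", sep="\t", index=False)
        df = pd.DataFrame(rows)
        _write(df, out / "demography.tsv", cfg)
        return df

    run_stage("demography", stage_demography)

    # ---- isolation with migration ----------------------------------------
    def stage_im():
        results = {}
        for pair in cfg.im_pairs:
            imcfg = im.IMConfig(chain_length=cfg.im_cycles,
                                burn_in=cfg.im_burnin, seed=cfg.seed)
            post = im.run_im_mcmc(aln, tuple(pair), imcfg)
            results[post.pair] = post
            pd.DataFrame({"theta_grid": post.theta_grid,
                          "theta_posterior": post.theta_posterior,
                          "M_grid": post.M_grid,
                          "M_posterior": post.M_posterior,
                          "T_grid": post.T_grid,
                          "T_posterior": post.T_posterior}).to_csv(
                out / f"im_posterior_{post.pair[0]}_{post.pair[1]}.tsv",
                sep="\t", index=False)
        df = im.im_summary_table(results, rm)
        _write(df, out / "im_summary.tsv", cfg)
        return df

    if cfg.run_im and cfg.im_pairs:
        run_stage("im", stage_im)

    (out / "status.json").write_text(json.dumps(status, indent=1))
    return status
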