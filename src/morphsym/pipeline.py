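"""End-to-end orchestration of the symmetry + modularity analysis.

One master seed deterministically spawns per-stage seeds; every stage
writes its own files so any stage can be rerun in isolation, and a
MANIFEST records which stages completed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import asymmetry, modularity, synthetic
from .io import (
    LandmarkDataset,
    ModulePartition,
    PairingScheme,
    load_analysis_config,
    read_tps,
    write_metadata,
    write_tps,
)
from .procrustes import decompose_symmetry, regress_out_size

__all__ = ["PipelineConfig", "run_pipeline"]

MIN_ITER = 100


@dataclass
class PipelineConfig:
    """Inputs, iteration counts and seed for a full analysis run."""

    outdir: str = "morphsym_out"
    tps_path: str | None = None
    metadata_path: str | None = None
    config_path: str | None = None  # pairing/partition YAML; default fixture
    synthetic: synthetic.SyntheticParams | None = None
    anova_permutations: int = 1000
    mantel_iterations: int = 5000
    mantel_permutations: int = 999
    cr_permutations: int = 999
    modularity_rounds: int = 10000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "anova_permutations",
            "mantel_iterations",
            "mantel_permutations",
            "cr_permutations",
            "modularity_rounds",
        ):
            if getattr(self, name) < MIN_ITER:
                raise ValueError(f"{name} must be >= {MIN_ITER}")
        if self.tps_path is None and self.synthetic is None:
            raise ValueError("either tps_path or synthetic parameters required")


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(
    config: PipelineConfig,
    scheme: PairingScheme | None = None,
    partitions: list[ModulePartition] | None = None,
) -> dict:
    """Run every analysis stage and write a report bundle to ``outdir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if scheme is None or partitions is None:
        scheme, partitions = load_analysis_config(config.config_path)
    parts = {p.name: p for p in partitions}
    dev = parts.get("developmental")
    seeds = _stage_seeds(config.seed, 8)
    manifest: list[str] = []
    results: dict = {}
    log: list[str] = [f"master_seed={config.seed}", f"stage_seeds={seeds}"]

    # --- data -------------------------------------------------------------
    if config.tps_path is not None:
        dataset: LandmarkDataset = read_tps(config.tps_path, config.metadata_path)
        log.append(f"input={config.tps_path}")
    else:
        params = config.synthetic
        params.seed = seeds[0]
        dataset, truth = synthetic.generate_dataset(params, scheme, dev)
        write_tps(dataset, out / "synthetic.tps")
        write_metadata(dataset, out / "synthetic_metadata.csv")
        results["truth"] = truth
        log.append(f"generated synthetic dataset with seed {seeds[0]}")
    dataset.validate(require_sex=True)
    manifest.append("data")

    # --- decomposition ----------------------------------------------------
    comp = decompose_symmetry(dataset, scheme)
    results["components"] = comp
    cols = [f"lm{i}_{c}" for i in range(1, scheme.n_landmarks + 1) for c in "xy"]
    pd.DataFrame(comp.flat_symmetric(), index=comp.specimen_ids, columns=cols).to_csv(
        out / "symmetric_component.csv"
    )
    pd.DataFrame(comp.flat_asymmetric(), index=comp.specimen_ids, columns=cols).to_csv(
        out / "asymmetric_component.csv"
    )
    (out / "alignment_meta.json").write_text(
        json.dumps(comp.alignment_meta, indent=2)
    )
    manifest.append("decomposition")

    # --- Procrustes ANOVA -------------------------------------------------
    anova = asymmetry.procrustes_anova(
        comp, permutations=config.anova_permutations, seed=seeds[1]
    )
    anova.rows.to_csv(out / "procrustes_anova.csv", index=False)
    (out / "procrustes_anova.txt").write_text(anova.to_text() + "\n")
    results["anova"] = anova
    manifest.append("anova")

    # --- asymmetry profiles -----------------------------------------------
    profile = asymmetry.lr_asym_profile(comp, scheme)
    prof_f = asymmetry.ztest_profile(profile.subset_sex("F"))
    prof_m = asymmetry.ztest_profile(profile.subset_sex("M"))
    fa_prof = asymmetry.ztest_profile(
        asymmetry.lr_asym_profile(comp, scheme, remove_directional=True)
    )
    prof_f.stats.to_csv(out / "profile_female.csv", index=False)
    prof_m.stats.to_csv(out / "profile_male.csv", index=False)
    fa_prof.stats.to_csv(out / "profile_fluctuating.csv", index=False)
    sex_cmp = asymmetry.compare_profiles_between_sexes(prof_f, prof_m)
    sex_cmp.to_csv(out / "profile_sex_comparison.csv", index=False)
    results["profiles"] = {"F": prof_f, "M": prof_m, "FA": fa_prof, "sex": sex_cmp}
    manifest.append("profiles")

    # --- Mantel -----------------------------------------------------------
    if dev is not None:
        mantel = {
            sex: asymmetry.mantel_modules(
                comp,
                dev,
                iterations=config.mantel_iterations,
                permutations=config.mantel_permutations,
                seed=seeds[2] + i,
                sex=sex,
            )
            for i, sex in enumerate(("F", "M"))
        }
        t, p = asymmetry.compare_mantel_distributions(mantel["F"], mantel["M"])
        pd.DataFrame(
            {
                "sex": ["F", "M"],
                "r": [mantel["F"].r_point, mantel["M"].r_point],
                "p_perm": [mantel["F"].p_perm, mantel["M"].p_perm],
                "r_boot_mean": [
                    mantel["F"].r_distribution.mean(),
                    mantel["M"].r_distribution.mean(),
                ],
            }
        ).to_csv(out / "mantel.csv", index=False)
        (out / "mantel_sex_comparison.txt").write_text(
            f"paired t = {t:.4f}, p = {p:.3e}\n"
        )
        results["mantel"] = {**mantel, "t": t, "p": p}
        manifest.append("mantel")

    # --- modular signal per sex -------------------------------------------
    resid = regress_out_size(comp)
    multi = [p for p in partitions if p.module_count >= 2]
    signal_rows = []
    results["signal"] = {}
    for i, sex in enumerate(("F", "M")):
        mask = comp.sex_mask(sex)
        shape_sex = resid[mask]
        sig = [
            modularity.cr_effect_size(
                shape_sex, p, permutations=config.cr_permutations, seed=seeds[3] + i
            )
            for p in multi
        ]
        cmp_ = modularity.compare_modular_signal(sig)
        results["signal"][sex] = {"results": sig, "comparison": cmp_}
        for r in sig:
            signal_rows.append(
                {
                    "sex": sex,
                    "model": r.partition_name,
                    "CR": r.cr,
                    "Z_CR": r.z_cr_mean,
                    "ci_lo": r.ci95[0],
                    "ci_hi": r.ci95[1],
                    "group": cmp_.grouping[r.partition_name],
                }
            )
    pd.DataFrame(signal_rows).to_csv(out / "modular_signal.csv", index=False)
    manifest.append("modular_signal")

    # --- EMMLi-style model selection per sex --------------------------------
    registry = modularity.enumerate_covariation_variants(partitions)
    best_by_sex = {}
    emmli_tables = []
    for sex in ("F", "M"):
        mask = comp.sex_mask(sex)
        fit = modularity.emmli_fit(resid[mask], registry, n_eff=int(mask.sum()))
        tab = fit.table.copy()
        tab.insert(0, "sex", sex)
        emmli_tables.append(tab)
        best_by_sex[sex] = fit.best_model
        results.setdefault("emmli", {})[sex] = fit
    pd.concat(emmli_tables).to_csv(out / "emmli.csv", index=False)
    manifest.append("emmli")

    # --- modularity tests ---------------------------------------------------
    mt_rows = []
    results["modularity_test"] = {}
    base_of = {m.name: m.partition for m in registry}
    for i, sex in enumerate(("F", "M")):
        mask = comp.sex_mask(sex)
        targets = {"developmental": dev} if dev is not None else {}
        best_part = base_of.get(best_by_sex[sex])
        if best_part is not None and best_part.module_count >= 2:
            targets[f"best({best_part.name})"] = best_part
        for label, part in targets.items():
            mt = modularity.modularity_test(
                resid[mask],
                part,
                rounds=config.modularity_rounds,
                seed=seeds[4] + i,
            )
            results["modularity_test"][(sex, label)] = mt
            mt_rows.append(
                {
                    "sex": sex,
                    "target": label,
                    "cr_observed_mean": mt.cr_observed_mean,
                    "p": mt.p,
                    "rounds": mt.rounds,
                }
            )
    pd.DataFrame(mt_rows).to_csv(out / "modularity_test.csv", index=False)
    manifest.append("modularity_test")

    # --- bundle metadata ----------------------------------------------------
    summary = [
        "morphsym analysis summary",
        "=" * 40,
        f"specimens: {comp.n_specimens} "
        f"(F={int(comp.sex_mask('F').sum())}, M={int(comp.sex_mask('M').sum())}), "
        f"landmarks: {comp.n_landmarks}",
        "",
        "Procrustes ANOVA:",
        anova.to_text(),
        "",
        "Best covariation model by AICc: "
        + ", ".join(f"{s}: {m}" for s, m in best_by_sex.items()),
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    cfg = {k: v for k, v in asdict(config).items() if k != "synthetic"}
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    results["manifest"] = manifest
    return results
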