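"""End-to-end analysis pipeline and results-bundle assembly.

Each stage reads and writes plain-text artifacts inside one output
directory so runs are inspectable and resumable:

``records.csv``/``covariates.csv`` (input data), ``sequences_wide.csv``,
``transition_rates.csv``, ``substitution_costs.csv``, ``distances.csv``,
``cluster_labels.csv``/``cluster_diagnostics.json``/``dendrogram.txt``,
``player_typing.csv``/``association.json``, ``transition_tests.json``,
``trait_models.json``/``bout_model.json``, ``sync.json`` and a
``results.json`` index of headline numbers.

Every stochastic step draws its seed from one master seed recorded in the
results index, so a full run is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .clustering import dendrogram_newick, select_k
from .inference import bonferroni, bout_table, cmh_test, linear_model_traits, \
    poisson_bout_model, traits_table
from .om import pairwise_distances, substitution_costs_from_rates
from .players import classify_players, crosstab, fisher_exact_rxc, \
    kendall_tau_b, tally_events
from .seqcore import DEFAULT_ALPHABET, transition_rates
from .sync import cyclic_shift_null, expected_simultaneity, shared_toy_stats, \
    sync_profile
from .synth import SynthConfig, generate_dataset

log = logging.getLogger("playseq")

__all__ = ["PipelineConfig", "simulate_to_dir", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Tunable settings of one pipeline run."""

    indel: float = 1.0
    k_min: int = 2
    k_max: int = 8
    ci_level: float = 0.90
    ci_method: str = "beta"
    sync_state: str = "ObjP"
    sync_k: int = 2
    n_perm: int = 999
    seed: int = 0
    n_intervals: int = 360


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def simulate_to_dir(config: SynthConfig, out_dir: str | Path,
                    seed: int | None = None) -> dict:
    """Generate a dataset and write records, covariates, planted truth and
    the generator configuration into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, covariates, truth = generate_dataset(config, seed=seed)
    pio.write_records(records, out / "records.csv")
    covariates.to_csv(out / "covariates.csv")
    truth.pigs.to_csv(out / "ground_truth.csv", index=False)
    cfg = asdict(config)
    (out / "generator_config.yaml").write_text(_to_yaml(cfg))
    manifest = {
        "n_records": len(records),
        "n_animals": int(covariates.shape[0]),
        "n_groups": config.n_groups,
        "T": config.T,
        "seed": config.seed if seed is None else seed,
    }
    _dump_json(manifest, out / "simulate_manifest.json")
    log.info("simulate: wrote %d records for %d animals to %s",
             manifest["n_records"], manifest["n_animals"], out)
    return manifest


def _to_yaml(obj, indent: int = 0) -> str:
    # plain hierarchical key-value rendering (subset of YAML)
    pad = "  " * indent
    lines = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)) and v:
                lines.append(f"{pad}{k}:")
                lines.append(_to_yaml(v, indent + 1))
            else:
                lines.append(f"{pad}{k}: {v if v is not None else 'null'}")
    elif isinstance(obj, list):
        for v in obj:
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}-")
                lines.append(_to_yaml(v, indent + 1))
            else:
                lines.append(f"{pad}- {v}")
    else:
        lines.append(f"{pad}{obj}")
    return "\n".join(lines)


def _transition_comparison(seqs, typings, alphabet) -> dict:
    """Initiator-vs-joiner transition usage per state pair, CMH over group
    strata with Bonferroni correction."""
    ij_of = {t.animal_id: t.ij_class for t in typings}
    groups: dict[str, list] = {}
    for s in seqs:
        groups.setdefault(s.group_id, []).append(s)
    comparisons = {}
    pvals = []
    names = []
    a = alphabet.size
    per_animal_counts = {
        s.animal_id: transition_rates([s], alphabet).counts for s in seqs
    }
    for i in range(a):
        for j in range(a):
            if i == j:
                continue
            strata = []
            for gseqs in groups.values():
                table = np.zeros((2, 2))
                for s in gseqs:
                    cls = ij_of.get(s.animal_id)
                    if cls not in ("initiator", "joiner"):
                        continue
                    row = 0 if cls == "initiator" else 1
                    counts = per_animal_counts[s.animal_id]
                    made = counts[i, j]
                    other = counts[i].sum() - made
                    table[row, 0] += made
                    table[row, 1] += other
                if table.sum() > 0:
                    strata.append(table)
            name = f"{alphabet.states[i]}->{alphabet.states[j]}"
            try:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    stat, df, p = cmh_test(strata)
                comparisons[name] = {"cmh": stat, "df": df, "p": p}
                pvals.append(p)
                names.append(name)
            except ValueError as exc:
                comparisons[name] = {"error": str(exc)}
    for name, adj in zip(names, bonferroni(pvals)):
        comparisons[name]["p_bonferroni"] = adj
    return comparisons


def _model_summary(fit) -> dict:
    return {
        "params": {k: float(v) for k, v in fit.params.items()},
        "bse": {k: float(v) for k, v in fit.bse.items()},
        "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
    }


def run_pipeline(
    records_path: str | Path,
    covariates_path: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute the full analysis chain on a long-format record file.

    Stages: sequence construction, pooled transition rates, OM distances,
    Ward clustering with k selection, player typing and association,
    transition-rate comparison, trait and bout-duration models, and the
    synchrony analysis.  Returns the results index (also written as
    ``results.json``).
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alphabet = DEFAULT_ALPHABET
    rng = np.random.default_rng(cfg.seed)

    log.info("build: reading records from %s", records_path)
    df = pd.read_csv(records_path, keep_default_na=False, na_values=[])
    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(covariates_path, index_col=0)
    seqs = pio.sequences_from_frame(df, alphabet, cfg.n_intervals, covariates)
    if len(seqs) < 2:
        raise ValueError("pipeline needs at least two animals")
    pio.write_wide(seqs, out / "sequences_wide.csv")
    log.info("build: %d sequences of length %d", len(seqs), cfg.n_intervals)

    tm = transition_rates(seqs, alphabet)
    pd.DataFrame(tm.P, index=alphabet.states, columns=alphabet.states).to_csv(
        out / "transition_rates.csv"
    )
    sc = substitution_costs_from_rates(tm)
    pd.DataFrame(sc.SC, index=alphabet.states, columns=alphabet.states).to_csv(
        out / "substitution_costs.csv"
    )

    log.info("distances: %d x %d OM matrix", len(seqs), len(seqs))
    D = pairwise_distances(seqs, sc, indel=cfg.indel)
    pio.write_distance_matrix(D.ids, D.D, out / "distances.csv")

    log.info("cluster: selecting k in %d..%d", cfg.k_min, cfg.k_max)
    sol = select_k(D, range(cfg.k_min, cfg.k_max + 1))
    pd.DataFrame({"animal_id": D.ids, "cluster": sol.labels}).to_csv(
        out / "cluster_labels.csv", index=False
    )
    _dump_json(
        {
            "k": sol.k,
            "avg_silhouette": sol.avg_silhouette,
            "hubert_c": sol.hubert_c,
            "best_k_by_c": sol.best_k_by_c,
            "diagnostics": {str(k): v for k, v in sol.diagnostics.items()},
        },
        out / "cluster_diagnostics.json",
    )
    (out / "dendrogram.txt").write_text(
        dendrogram_newick(sol.merge_tree, D.ids) + "\n"
    )

    log.info("classify: typing %d animals", len(seqs))
    by_animal: dict[str, list] = {}
    for r in pio.frame_to_records(df):
        by_animal.setdefault(r.animal_id, []).append(r)
    typings = classify_players(
        [tally_events(v) for v in by_animal.values()],
        level=cfg.ci_level, method=cfg.ci_method,
    )
    typing_df = pd.DataFrame(
        [
            {
                "animal_id": t.animal_id, "n_initiate": t.n_initiate,
                "n_join": t.n_join, "n_alone": t.n_alone,
                "n_together": t.n_together, "ij_class": t.ij_class,
                "ss_class": t.ss_class,
            }
            for t in typings
        ]
    )
    typing_df.to_csv(out / "player_typing.csv", index=False)
    table = crosstab(typings)
    pd.DataFrame(
        table.counts, index=table.row_labels, columns=table.col_labels
    ).to_csv(out / "crosstab.csv")
    association = association_report(table, seed=int(rng.integers(2 ** 31)))
    _dump_json(association, out / "association.json")

    log.info("transitions: stratified initiator/joiner comparison")
    trans = _transition_comparison(seqs, typings, alphabet)
    _dump_json(trans, out / "transition_tests.json")

    log.info("models: complexity traits and bout durations")
    ij_of = {t.animal_id: t.ij_class for t in typings}
    traits = traits_table(seqs, alphabet)
    traits["player_type"] = traits["animal_id"].map(ij_of)
    trait_models = {}
    for response in ("entropy", "turbulence", "complexity"):
        fit, anova = linear_model_traits(traits, response)
        trait_models[response] = {
            "anova": {
                str(term): {
                    "F": None if pd.isna(row.get("F")) else float(row["F"]),
                    "p": None if pd.isna(row.get("PR(>F)")) else float(row["PR(>F)"]),
                }
                for term, row in anova.iterrows()
            }
        }
    _dump_json(trait_models, out / "trait_models.json")
    bouts = bout_table(seqs)
    bouts["player_type"] = bouts["animal_id"].map(ij_of)
    bout_fit = poisson_bout_model(bouts)
    _dump_json(_model_summary(bout_fit), out / "bout_model.json")

    log.info("sync: per-group simultaneity analysis")
    groups: dict[str, list] = {}
    for s in seqs:
        groups.setdefault(s.group_id, []).append(s)
    sync_out = {}
    for gid, gseqs in sorted(groups.items()):
        prof = sync_profile(gseqs, cfg.sync_state)
        code = alphabet.index(cfg.sync_state)
        marginals = [float((s.codes == code).mean()) for s in gseqs]
        res = cyclic_shift_null(
            gseqs, cfg.sync_state, k=cfg.sync_k, n_perm=cfg.n_perm,
            seed=int(rng.integers(2 ** 31)),
        )
        grecs = [r for v in by_animal.values() for r in v
                 if v and v[0].group_id == gid]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            toys = shared_toy_stats(grecs)
        sync_out[gid] = {
            "marginal_counts": prof.marginal.tolist(),
            "observed_share_ge_k": res.observed_share,
            "expected_share_ge_k_independent": expected_simultaneity(
                marginals, cfg.sync_k
            ),
            "p_cyclic_shift": res.p_value,
            "ci95": list(res.ci95),
            "shared_both_toys": {str(k): v for k, v in toys.items()},
        }
    _dump_json(sync_out, out / "sync.json")

    results = {
        "n_animals": len(seqs),
        "n_groups": len(groups),
        "sequence_length": cfg.n_intervals,
        "cluster_k": sol.k,
        "avg_silhouette": sol.avg_silhouette,
        "hubert_c": sol.hubert_c,
        "tau_b": association["tau_b"],
        "tau_b_ase": association["ase"],
        "seed": cfg.seed,
        "artifacts": sorted({p.name for p in out.iterdir()} | {"results.json"}),
    }
    _dump_json(results, out / "results.json")
    log.info("run complete: results index at %s", out / "results.json")
    return results


def association_report(table, seed: int | None = None, n_mc: int = 20000) -> dict:
    """tau-b, its ASE and the Fisher exact p for a cross table.

    A table with an entirely tied margin (every animal in one row or
    column class) has no defined tau-b; the report then carries nulls and
    a note instead of failing the whole pipeline.
    """
    counts = table.counts if hasattr(table, "counts") else np.asarray(table)
    out = {"n": int(np.asarray(counts).sum())}
    try:
        tau, ase = kendall_tau_b(table)
        out["tau_b"] = float(tau)
        out["ase"] = float(ase)
    except ValueError as exc:
        out["tau_b"] = None
        out["ase"] = None
        out["note"] = str(exc)
    out["fisher_p"] = float(fisher_exact_rxc(table, n_mc=n_mc, seed=seed))
    return out
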