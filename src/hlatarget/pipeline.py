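"""End-to-end orchestration: simulate a full scenario, run every analysis
stage from one configuration, and write the artifact directory.

Every output table starts with comment lines recording the seed and a hash
of the merged configuration, so artifacts are traceable and two runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import filtering, io, lfq, motifs, surfaceome, synthetic
from .config import RunConfig, config_hash
from .spectra import validate_pair

__all__ = [
    "simulate_scenario",
    "run_all",
    "reference_panel_report",
    "load_reference_panel",
]

logger = logging.getLogger("hlatarget")

A2_LIKE_ANCHORS = {2: (("L", "M"), 0.9), 9: (("L", "V"), 0.9)}
A3_LIKE_ANCHORS = {1: (("K", "R"), 0.9), 9: (("K", "R"), 0.9)}
CANONICAL_LENGTH_DIST = {9: 0.65, 10: 0.2, 11: 0.1, 8: 0.03, 12: 0.02}


def _write_with_header(df: pd.DataFrame, path: Path, config: RunConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed}\n# config={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index)


def simulate_scenario(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input for the configured scenario.

    Writes a PSM table, blank/iRT lists, a rank table (from the PSSM
    surrogate), endogenous/synthetic MGF pairs, LFQ and surface matrices
    with group maps, a TM-prediction table and annotation lists; returns
    the path of each artifact by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config["simulate"]
    seed = config.seed
    rng = np.random.default_rng(seed)

    model = synthetic.make_motif_model("A*02:01", A2_LIKE_ANCHORS, length=9)
    length_dist = {int(k): float(v) for k, v in sim["length_dist"].items()}
    peptides = synthetic.sample_peptides(
        model, sim["n_true_peptides"], length_dist, seed=rng
    )
    records, blank_set, truth = synthetic.make_psm_dataset(
        peptides,
        n_decoy=sim["n_decoy"],
        n_irt=sim["n_irt"],
        n_blank=sim["n_blank"],
        n_modified=sim["n_modified"],
        samples=("line1", "line2", "line3"),
        seed=seed,
    )
    paths: dict[str, Path] = {}

    paths["psm_table"] = outdir / "psm_table.tsv"
    io.write_psm_table(records, paths["psm_table"])
    paths["blank_peptides"] = outdir / "blank_peptides.txt"
    Path(paths["blank_peptides"]).write_text("\n".join(sorted(blank_set)) + "\n")
    paths["irt_peptides"] = outdir / "irt_peptides.txt"
    Path(paths["irt_peptides"]).write_text("\n".join(synthetic.IRT_PEPTIDES) + "\n")

    # surrogate percent ranks, one PSSM per length class
    nonamers = sorted({p for p in peptides if len(p) == 9})
    ranks: dict[str, float] = {}
    by_length: dict[int, list[str]] = {}
    for p in sorted(set(peptides)):
        by_length.setdefault(len(p), []).append(p)
    for length, peps in by_length.items():
        pfm = motifs.build_pfm(peps, pseudocount=1.0)
        ranks.update(
            motifs.percent_rank_surrogate(peps, pfm, n_background=2000, seed=seed + length)
        )
    paths["rank_table"] = outdir / "rank_table.tsv"
    io.write_rank_table(
        [io.BindingRank(p, model.allele, r) for p, r in sorted(ranks.items())],
        paths["rank_table"],
    )

    n_pairs = min(sim["n_validation_pairs"], len(nonamers))
    endo, synt = [], []
    for pep in nonamers[:n_pairs]:
        e, s = synthetic.simulate_spectrum_pair(
            pep,
            noise_cv=sim["noise_cv"],
            rt_shift_min=float(np.round(rng.normal(0.0, 1.5), 2)),
            n_noise_peaks=sim["n_noise_peaks"],
            rt_base_min=float(np.round(rng.uniform(20.0, 90.0), 1)),
            seed=rng,
        )
        endo.append(e)
        synt.append(s)
    paths["endogenous_mgf"] = outdir / "endogenous.mgf"
    paths["synthetic_mgf"] = outdir / "synthetic.mgf"
    io.write_mgf(endo, paths["endogenous_mgf"])
    io.write_mgf(synt, paths["synthetic_mgf"])

    lfq_cfg = sim["lfq"]
    matrix, lfq_truth = synthetic.simulate_lfq_experiment(seed=seed, **lfq_cfg)
    paths["lfq_matrix"] = outdir / "lfq_matrix.tsv"
    paths["lfq_groups"] = outdir / "lfq_groups.tsv"
    io.write_lfq_matrix(matrix, paths["lfq_matrix"], paths["lfq_groups"])
    paths["lfq_truth"] = outdir / "lfq_truth.txt"
    Path(paths["lfq_truth"]).write_text("\n".join(sorted(lfq_truth.de_proteins)) + "\n")

    # surface matrix: 7 lines x 4 replicates over a protein subset
    surf, _ = synthetic.simulate_lfq_experiment(
        n_proteins=300,
        n_per_group=4,
        frac_de=0.0,
        groups=("lineA", "lineB"),
        seed=seed + 1,
    )
    paths["surface_matrix"] = outdir / "surface_matrix.tsv"
    paths["surface_groups"] = outdir / "surface_groups.tsv"
    io.write_lfq_matrix(surf, paths["surface_matrix"], paths["surface_groups"])

    fasta = {
        acc: "".join(rng.choice(list(io.AMINO_ACIDS), size=int(rng.integers(80, 200))))
        for acc in surf.proteins[:100]
    }
    paths["proteome_fasta"] = outdir / "proteome.fasta"
    io.write_fasta(fasta, paths["proteome_fasta"])
    tm_preds = [
        io.TmPrediction(acc, int(rng.integers(0, 8))) for acc in surf.proteins
    ]
    paths["tm_table"] = outdir / "tm_table.tsv"
    io.write_tm_table(tm_preds, paths["tm_table"])

    proteins = sorted({p for r in records for p in r.proteins if not r.is_decoy})
    dbs, _ = synthetic.make_annotation_fixtures(
        sorted(set(peptides)), proteins, sim["overlap_fractions"], seed=seed
    )
    for db in dbs:
        paths[f"db_{db.name}"] = outdir / f"db_{db.name}.txt"
        io.write_named_list(db, paths[f"db_{db.name}"])
    return paths


def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate inputs then run every stage, writing one artifact per stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = simulate_scenario(config, outdir / "inputs")
    artifacts: dict[str, Path] = dict(inputs)

    # --- filter ladder -----------------------------------------------------
    logger.info("stage filter: reading %s", inputs["psm_table"])
    psms = io.parse_psm_table(inputs["psm_table"])
    blank = set(Path(inputs["blank_peptides"]).read_text().split())
    irt = set(Path(inputs["irt_peptides"]).read_text().split())
    fcfg = filtering.FilterConfig(
        blank_peptides=frozenset(blank),
        irt_peptides=frozenset(irt),
        **config["filter"],
    )
    report = filtering.apply_filter_ladder(psms, fcfg)
    summary = pd.DataFrame(
        [{"step": k, "removed": v} for k, v in report.removed.items()]
        + [
            {"step": "input", "removed": report.n_input},
            {"step": "retained", "removed": report.n_retained},
        ]
    )
    artifacts["filter_summary"] = outdir / "filter_summary.tsv"
    _write_with_header(summary, artifacts["filter_summary"], config, index=False)
    retained_df = pd.DataFrame(
        [
            {
                "sequence": e.sequence,
                "score": e.score,
                "q_value": e.q_value,
                "proteins": ";".join(sorted(e.proteins)),
                "samples": ";".join(sorted(e.samples)),
            }
            for e in sorted(report.retained, key=lambda e: e.sequence)
        ]
    )
    artifacts["retained_peptides"] = outdir / "retained_peptides.tsv"
    _write_with_header(retained_df, artifacts["retained_peptides"], config, index=False)

    # --- motif + length ----------------------------------------------------
    sequences = sorted(e.sequence for e in report.retained)
    counts, fractions = motifs.length_distribution(sequences)
    ldist = pd.DataFrame(
        {"length": list(counts), "count": list(counts.values()),
         "fraction": [fractions.get(l, 0.0) for l in counts]}
    )
    artifacts["length_distribution"] = outdir / "length_distribution.tsv"
    _write_with_header(ldist, artifacts["length_distribution"], config, index=False)
    nonamers = [s for s in sequences if len(s) == 9]
    mcfg = config["motif"]
    pfm = motifs.build_pfm(nonamers, pseudocount=mcfg["pseudocount"])
    artifacts["pfm"] = outdir / "pfm.tsv"
    _write_with_header(pfm, artifacts["pfm"], config, index=True)
    uniform = pd.DataFrame(
        np.full_like(pfm.to_numpy(), 1.0 / 20.0), index=pfm.index, columns=pfm.columns
    )
    diff = motifs.icelogo_diff(pfm, uniform, len(nonamers), alpha=mcfg["alpha"])
    artifacts["motif_diff"] = outdir / "motif_diff.tsv"
    _write_with_header(diff, artifacts["motif_diff"], config, index=False)

    # --- restriction -------------------------------------------------------
    ranks = io.parse_rank_table(inputs["rank_table"])
    by_pep: dict[str, dict[str, float]] = {}
    for r in ranks:
        by_pep.setdefault(r.peptide, {})[r.allele] = r.percent_rank
    restr_rows = []
    restrictions = {}
    for pep in sequences:
        if pep not in by_pep:
            continue
        call = motifs.assign_restriction(by_pep[pep], sb_only=config["restriction"]["sb_only"])
        restrictions[pep] = call
        restr_rows.append(
            {
                "peptide": pep,
                "allele": call[0] if call else "",
                "category": call[1] if call else "unassigned",
                "best_rank": min(by_pep[pep].values()),
            }
        )
    artifacts["restriction_table"] = outdir / "restriction_table.tsv"
    _write_with_header(pd.DataFrame(restr_rows), artifacts["restriction_table"], config, index=False)

    # --- annotation --------------------------------------------------------
    dbs = [
        io.parse_named_list(inputs[f"db_{name}"], name, synthetic.DB_KINDS[name])
        for name in config["simulate"]["overlap_fractions"]
    ]
    annotated, overlap_counts = ann.annotate(report.retained, dbs, restrictions)
    flag_df = pd.DataFrame(
        [
            {"sequence": a.sequence, **{k: int(v) for k, v in a.flags.items()}}
            for a in sorted(annotated, key=lambda a: a.sequence)
        ]
    )
    artifacts["annotated_peptides"] = outdir / "annotated_peptides.tsv"
    _write_with_header(flag_df, artifacts["annotated_peptides"], config, index=False)
    per_sample_sets = {
        s: {e.sequence for e in report.retained if s in e.samples}
        for s in sorted({s for e in report.retained for s in e.samples})
    }
    inter = ann.set_intersections(per_sample_sets)
    inter_df = pd.DataFrame(
        [{"combination": "&".join(c), "count": n} for c, n in inter.items()]
    )
    artifacts["upset_counts"] = outdir / "upset_counts.tsv"
    _write_with_header(inter_df, artifacts["upset_counts"], config, index=False)

    # --- spectral validation -----------------------------------------------
    endo = io.parse_mgf(inputs["endogenous_mgf"])
    synt = io.parse_mgf(inputs["synthetic_mgf"])
    vcfg = config["validation"]
    vrows = []
    for e, s in zip(endo, synt):
        pep = e.title.rsplit("_", 1)[0]
        res = validate_pair(
            e, s, pep,
            r_min=vcfg["r_min"],
            rt_window_min=vcfg["rt_window_min"],
            rt_rule_enabled=vcfg["rt_rule_enabled"],
            tol_da=vcfg["tol_da"],
        )
        vrows.append(
            {
                "peptide": res.peptide,
                "pearson_r": round(res.pearson_r, 4),
                "rt_endogenous_min": res.rt_endogenous_min,
                "rt_synthetic_min": res.rt_synthetic_min,
                "n_matched_fragments": res.n_matched_fragments,
                "decision": "pass" if res.decision else "fail",
            }
        )
    artifacts["validation_table"] = outdir / "validation_table.tsv"
    _write_with_header(pd.DataFrame(vrows), artifacts["validation_table"], config, index=False)

    # --- differential expression -------------------------------------------
    matrix = io.parse_lfq_matrix(inputs["lfq_matrix"], inputs["lfq_groups"])
    prep = lfq.preprocess(matrix)
    imputed = lfq.impute(prep, lfq.ImputationParams(seed=config.seed, **config["imputation"]))
    de = lfq.differential_test(imputed, **config["de"])
    artifacts["de_table"] = outdir / "de_table.tsv"
    _write_with_header(de.round(6), artifacts["de_table"], config, index=True)
    artifacts["volcano_table"] = outdir / "volcano_table.tsv"
    _write_with_header(lfq.volcano_table(de).round(6), artifacts["volcano_table"], config, index=True)

    # --- surfaceome ---------------------------------------------------------
    surf = io.parse_lfq_matrix(inputs["surface_matrix"], inputs["surface_groups"])
    scfg = config["surfaceome"]
    detected = surfaceome.detection_sets(surf, min_replicates=scfg["min_replicates"])
    core = surfaceome.shared_core(detected.values())
    tm = io.parse_tm_table(inputs["tm_table"])
    membrane = surfaceome.tm_filter(tm, sorted(core), min_helices=scfg["min_helices"])
    log_surf = lfq.preprocess(surf, min_valid=1)
    cspa_db = io.parse_named_list(inputs["db_CSPA"], "CSPA", "protein")
    ranked = surfaceome.rank_surface(
        membrane, log_surf, k=scfg["top_k"], cspa=set(cspa_db.members)
    )
    artifacts["surface_table"] = outdir / "surface_table.tsv"
    _write_with_header(ranked.round(6), artifacts["surface_table"], config, index=True)

    logger.info("wrote %d artifacts to %s", len(artifacts), outdir)
    return artifacts


# ---------------------------------------------------------------------------
# bundled reference validation panel
# ---------------------------------------------------------------------------


def load_reference_panel() -> pd.DataFrame:
    """The bundled 12-peptide tumor-antigen validation panel.

    Columns: source protein, peptide, measured endogenous-vs-synthetic
    mirror Pearson R, and the two retention times (minutes).
    """
    with resources.files("hlatarget.data").joinpath("validation_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_panel_report(
    r_min: float = 0.9,
    rt_window_min: float = 3.0,
    rt_rule_enabled: bool = False,
) -> dict:
    """Apply the pass/fail rule to the bundled validation panel.

    Returns the decision table plus the pass count and the minimum and
    maximum R among passing peptides.
    """
    panel = load_reference_panel()
    passes = panel["pearson_r"] >= r_min
    if rt_rule_enabled:
        passes &= (
            panel["rt_endogenous_min"] - panel["rt_synthetic_min"]
        ).abs() <= rt_window_min
    table = panel.assign(decision=np.where(passes, "pass", "fail"))
    passing_r = panel.loc[passes, "pearson_r"]
    return {
        "table": table,
        "n": len(panel),
        "n_pass": int(passes.sum()),
        "min_passing_r": float(passing_r.min()) if passes.any() else float("nan"),
        "max_passing_r": float(passing_r.max()) if passes.any() else float("nan"),
    }
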