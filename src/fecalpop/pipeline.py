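"""End-to-end orchestration: simulate → consensus → individuals → statistics
→ phylogeny → clustering → source assignment, with a run manifest.

Every stage writes its outputs under the configured directory and records
them (with SHA-256 checksums) in ``manifest.json``; the global seed plus a
fixed per-stage offset seeds each stochastic stage, so single stages can be
re-run in isolation and a full rerun with the same config is bit-identical.
A stage failure halts downstream stages but preserves what was written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import assignment as asg
from . import consensus as cns
from . import identity as idy
from . import io_formats as iof
from . import phylo
from . import popgen
from . import synthetic_data as syn
from .errors import FecalpopError

log = logging.getLogger(__name__)

STAGES = ("simulate", "consensus", "individuals", "stats", "phylo", "structure", "assign")
STAGE_SEED_OFFSETS = {name: 101 * (i + 1) for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    out_dir: str = "fecalpop_run"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: dict[str, Any] = field(default_factory=dict)
    consensus: dict[str, Any] = field(
        default_factory=lambda: {"het_threshold": 2, "hom_threshold": 5, "reliability_min": 0.99}
    )
    identity: dict[str, Any] = field(
        default_factory=lambda: {"one_mismatch_populations": ["CCA"], "min_shared_loci": 8}
    )
    stats: dict[str, Any] = field(
        default_factory=lambda: {"n_perm": 1000, "distance_model": "K2P"}
    )
    phylo: dict[str, Any] = field(default_factory=lambda: {"model": "K2P", "n_boot": 200})
    structure: dict[str, Any] = field(
        default_factory=lambda: {
            "k_range": [1, 2, 3, 4],
            "replicates_per_k": 3,
            "burn_in": 500,
            "run_length": 2500,
            "use_location_prior": True,
            "make_plot": False,
        }
    )
    assign: dict[str, Any] = field(default_factory=lambda: {"focal_population": "CCA"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise FecalpopError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                cur.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Mutable state threaded through the stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, Any] = {
            "seed": config.seed,
            "stages": {},
            "config": dataclasses.asdict(config),
        }
        self.table: Optional[pd.DataFrame] = None
        self.meta: Optional[pd.DataFrame] = None
        self.seqs: Optional[iof.SequenceSet] = None
        self.truth: Optional[syn.SimulatedTruth] = None
        self.truth_map: Optional[dict[str, str]] = None
        self.consensus: Optional[dict] = None
        self.error_rates: tuple[float, float] = (float("nan"), float("nan"))
        self.individuals: Optional[list[idy.Individual]] = None
        self.ind_array = None
        self.hap_of_sample: Optional[dict[str, str]] = None
        self.haplotypes: Optional[iof.SequenceSet] = None

    def record(self, stage: str, outputs: dict[str, Path], **info) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
            **info,
        }

    def stage_seed(self, stage: str) -> int:
        return (self.config.seed + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; returns the manifest."""
    run = PipelineRun(config)
    funcs = {
        "simulate": _stage_simulate,
        "consensus": _stage_consensus,
        "individuals": _stage_individuals,
        "stats": _stage_stats,
        "phylo": _stage_phylo,
        "structure": _stage_structure,
        "assign": _stage_assign,
    }
    for stage in STAGES:
        if not config.stages.get(stage, True):
            run.manifest["stages"][stage] = {"skipped": True}
            continue
        try:
            funcs[stage](run)
        except Exception as exc:  # halt downstream, keep partial outputs
            run.manifest["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
            log.error("stage %s failed: %s", stage, exc)
            break
    manifest_path = run.out / "manifest.json"
    manifest_path.write_text(json.dumps(run.manifest, indent=2, default=str))
    return run.manifest


def _stage_simulate(run: PipelineRun) -> None:
    params = dict(run.config.simulation)
    params.setdefault("seed", run.stage_seed("simulate"))
    sim_cfg = syn.SimulationConfig(**params)
    rng = np.random.default_rng(sim_cfg.seed)
    run.truth = syn.simulate_metapopulation(sim_cfg, rng)
    run.table, run.meta, run.seqs, run.truth_map = syn.sample_dung(run.truth, sim_cfg, rng)
    out = run.out
    iof.write_genotype_table(run.table, out / "genotypes.csv")
    iof.write_metadata(run.meta, out / "metadata.csv")
    iof.write_fasta(run.seqs, out / "mtdna.fasta")
    truth_df = pd.DataFrame(
        sorted(run.truth_map.items()), columns=["sample_id", "individual_id"]
    )
    truth_df.to_csv(out / "truth.csv", index=False)
    run.record(
        "simulate",
        {
            "genotypes": out / "genotypes.csv",
            "metadata": out / "metadata.csv",
            "mtdna": out / "mtdna.fasta",
            "truth": out / "truth.csv",
        },
        n_individuals=len(run.truth.individuals),
        n_samples=len(truth_df),
    )


def _stage_consensus(run: PipelineRun) -> None:
    p = run.config.consensus
    run.consensus = cns.call_consensus(
        run.table, het_threshold=p["het_threshold"], hom_threshold=p["hom_threshold"]
    )
    d_hat, f_hat = cns.estimate_error_rates(run.table, run.consensus)
    run.error_rates = (d_hat, f_hat)
    cns.genotype_reliability(
        run.consensus, run.table, d_hat, f_hat, reliability_threshold=p["reliability_min"]
    )
    arr = cns.consensus_to_array(run.consensus)
    out = run.out
    arr.to_frame().to_csv(out / "consensus.csv")
    qc = pd.DataFrame(
        {
            "sample_id": list(run.consensus),
            "n_called": [c.n_called for c in run.consensus.values()],
            "reliability": [c.reliability for c in run.consensus.values()],
            "flags": [";".join(c.flags) for c in run.consensus.values()],
        }
    )
    qc.to_csv(out / "consensus_qc.csv", index=False)
    run.record(
        "consensus",
        {"consensus": out / "consensus.csv", "qc": out / "consensus_qc.csv"},
        dropout_estimate=d_hat,
        false_allele_estimate=f_hat,
    )


def _stage_individuals(run: PipelineRun) -> None:
    p = run.config.identity
    meta = run.meta.set_index("sample_id")
    sexes = {
        sid: idy.assign_sex(iof.parse_sex_replicates(meta.loc[sid, "sex_replicates"]))
        for sid in meta.index
    }
    run.hap_of_sample, run.haplotypes = popgen.collapse_haplotypes(run.seqs)
    pops = {sid: meta.loc[sid, "population"] for sid in meta.index}
    usable = {s: c for s, c in run.consensus.items() if "all_loci_failed" not in c.flags}
    arr = cns.consensus_to_array(usable, populations=pops)
    individuals, audits, conflicts = idy.match_samples(
        arr,
        sexes=sexes,
        haplotypes=run.hap_of_sample,
        one_mismatch_populations=p["one_mismatch_populations"],
        min_shared_loci=p["min_shared_loci"],
    )
    run.individuals = individuals
    run.ind_array = idy.individuals_to_array(individuals, arr.loci)
    out = run.out
    rows = [
        {
            "individual_id": ind.individual_id,
            "population": ind.population,
            "sex": ind.sex,
            "haplotype": ind.haplotype_id,
            "n_samples": len(ind.member_sample_ids),
            "samples": ";".join(ind.member_sample_ids),
            "flags": ";".join(ind.flags),
        }
        for ind in individuals
    ]
    pd.DataFrame(rows).to_csv(out / "individuals.csv", index=False)
    pd.DataFrame([dataclasses.asdict(a) for a in audits]).to_csv(
        out / "merge_audit.csv", index=False
    )
    counts = (
        pd.DataFrame(rows).groupby("population").size().rename("n_individuals").to_frame()
    )
    counts["n_samples"] = meta.groupby("population").size()
    counts.to_csv(out / "population_counts.csv")
    freqs = {
        locus: run.ind_array.allele_freqs(l) for l, locus in enumerate(run.ind_array.loci)
    }
    pid = idy.probability_of_identity(freqs)
    (out / "identity_stats.json").write_text(
        json.dumps(
            {
                "cumulative_pid": pid.cumulative_pid,
                "cumulative_pid_sib": pid.cumulative_pid_sib,
            },
            indent=2,
        )
    )
    run.record(
        "individuals",
        {
            "individuals": out / "individuals.csv",
            "audit": out / "merge_audit.csv",
            "counts": out / "population_counts.csv",
            "identity": out / "identity_stats.json",
        },
        n_individuals=len(individuals),
        n_conflicts=len(conflicts),
    )


def _stage_stats(run: PipelineRun) -> None:
    p = run.config.stats
    out = run.out
    seed = run.stage_seed("stats")
    sample_pops = dict(zip(run.meta["sample_id"], run.meta["population"]))
    # one sequence per individual (first member sample)
    ind_seq_ids, ind_seqs, ind_seq_pops = [], [], {}
    for ind in run.individuals:
        sid = ind.member_sample_ids[0]
        ind_seq_ids.append(ind.individual_id)
        ind_seqs.append(run.seqs[sid])
        ind_seq_pops[ind.individual_id] = ind.population
    seqset = iof.SequenceSet(ind_seq_ids, ind_seqs)
    div = popgen.diversity(
        run.ind_array, seqset, ind_seq_pops, distance_model=p["distance_model"]
    )
    div.to_csv(out / "diversity.csv")
    theta = popgen.pairwise_fst_matrix(run.ind_array, n_perm=p["n_perm"], seed=seed)
    theta.to_frame().to_csv(out / "fst_microsat.csv")
    phi = popgen.pairwise_phi_st_matrix(
        seqset, ind_seq_pops, distance_model=p["distance_model"],
        n_perm=p["n_perm"], seed=seed + 7,
    )
    phi.to_frame().to_csv(out / "phi_st_mtdna.csv")
    run.record(
        "stats",
        {
            "diversity": out / "diversity.csv",
            "fst": out / "fst_microsat.csv",
            "phi_st": out / "phi_st_mtdna.csv",
        },
    )


def _stage_phylo(run: PipelineRun) -> None:
    p = run.config.phylo
    out = run.out
    tree = phylo.bootstrap_support(
        run.haplotypes, model=p["model"], n_boot=p["n_boot"], seed=run.stage_seed("phylo")
    )
    iof.write_newick(tree, out / "haplotypes.nwk")
    run.record("phylo", {"tree": out / "haplotypes.nwk"}, n_haplotypes=len(run.haplotypes))


def _stage_structure(run: PipelineRun) -> None:
    p = dict(run.config.structure)
    make_plot = p.pop("make_plot", False)
    out = run.out
    cfg = asg.SamplerConfig(
        k_range=tuple(p.get("k_range", (1, 2, 3, 4))),
        replicates_per_k=p.get("replicates_per_k", 3),
        burn_in=p.get("burn_in", 500),
        run_length=p.get("run_length", 2500),
        use_location_prior=p.get("use_location_prior", True),
        seed=run.stage_seed("structure"),
    )
    runs = asg.run_admixture_sampler(
        run.ind_array, cfg, locations=run.ind_array.populations
    )
    runs = asg.align_labels(runs)
    lvals = {}
    for r in runs:
        lvals.setdefault(r.k, []).append(r.ln_prob_data)
    evanno = asg.evanno_select(lvals)
    evanno.table.to_csv(out / "evanno.csv")
    best_k = evanno.selected_k or max(lvals, key=lambda k: np.mean(lvals[k]))
    best = max((r for r in runs if r.k == best_k), key=lambda r: r.ln_prob_data)
    qdf = best.to_frame(run.ind_array.populations)
    iof.write_qmatrix(qdf, out / f"qmatrix_K{best_k}.csv")
    outputs = {"evanno": out / "evanno.csv", "qmatrix": out / f"qmatrix_K{best_k}.csv"}
    if make_plot:
        outputs["barplot"] = _q_barplot(qdf, best_k, out / f"structure_K{best_k}.png")
    run.record("structure", outputs, selected_k=best_k, ambiguous=evanno.ambiguous)


def _q_barplot(qdf: pd.DataFrame, k: int, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qcols = [c for c in qdf.columns if c.startswith("Q")]
    df = qdf.sort_values("population")
    fig, ax = plt.subplots(figsize=(10, 3))
    bottom = np.zeros(len(df))
    x = np.arange(len(df))
    for col in qcols:
        ax.bar(x, df[col].to_numpy(), bottom=bottom, width=1.0)
        bottom += df[col].to_numpy()
    ax.set_xticks([])
    ax.set_ylabel("ancestry")
    ax.set_title(f"Admixture proportions, K={k}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _stage_assign(run: PipelineRun) -> None:
    p = run.config.assign
    focal_pop = p["focal_population"]
    out = run.out
    ids = run.ind_array.ids
    pops = run.ind_array.populations
    focal_idx = [i for i, pp in enumerate(pops) if pp == focal_pop]
    other_pops = sorted(set(pops) - {focal_pop})
    if not focal_idx or not other_pops:
        raise FecalpopError(f"no focal individuals or no candidates for {focal_pop!r}")
    focal = run.ind_array.subset(focal_idx)
    candidates = {
        pp: run.ind_array.subset([i for i, q in enumerate(pops) if q == pp])
        for pp in other_pops
    }
    hap_of_ind = {ind.individual_id: ind.haplotype_id for ind in run.individuals}
    cand_hap_counts: dict[str, dict[str, int]] = {pp: {} for pp in other_pops}
    for ind in run.individuals:
        if ind.population in cand_hap_counts and ind.haplotype_id:
            cnts = cand_hap_counts[ind.population]
            cnts[ind.haplotype_id] = cnts.get(ind.haplotype_id, 0) + 1
    df = asg.assign_source(
        focal,
        candidates,
        focal_haplotypes={i: h for i, h in hap_of_ind.items() if h},
        candidate_haplotype_counts=cand_hap_counts,
    )
    df.to_csv(out / "source_assignment.csv", index=False)
    summary = asg.summarise_assignment(df)
    summary.to_csv(out / "source_summary.csv", header=["fraction_top_ranked"])
    info = {"top_source": summary.idxmax() if len(summary) else None}
    outputs = {
        "assignment": out / "source_assignment.csv",
        "summary": out / "source_summary.csv",
    }
    if run.truth is not None:
        side_of = {
            p: s for p, s in run.truth.config.barrier_assignment.items() if p in other_pops
        }
        sides = asg.assign_side(df, side_of)
        sides.to_csv(out / "source_sides.csv", header=["side"])
        outputs["sides"] = out / "source_sides.csv"
        frac = sides.value_counts(normalize=True).to_dict()
        info["side_fractions"] = frac
    run.record("assign", outputs, **info)
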