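"""End-to-end driver: simulate -> callalleles -> copynum -> ase -> dnds.

The driver chains the package's stages over a shared output directory and
writes a manifest (seeds, config hash, per-stage row counts, output
checksums) so a run can be audited and reproduced.  In simulate mode every
input is generated from the canina-meiosis and pyrosequencing simulators,
so the full pipeline runs with zero external files: allele coding
sequences are evolved under the GY94 codon process, cloned with sequencing
error, re-called from the clones, assayed in silico, and pushed through
copy-number, allele-specific-transcription and molecular-evolution
analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_calling, ase, copy_number, io as cio
from .canina_genetics import make_founder
from .molevol import CodonAlignment, count_substitutions, m0_fit, ng86_dnds, tajima_rrt_batch
from .pyroseq_sim import AssayNoise, ExperimentDesign, ExpressionProfile, simulate_experiment

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "default_config"]


@dataclass
class RunConfig:
    """Pipeline configuration (see :func:`default_config` for the simulated
    LEAFY-like defaults)."""

    out_dir: str
    ploidy: int = 5
    locus: str = "LFY"
    n_codons: int = 300
    allele_divergence: float = 0.02  # branch length per allele, subs/codon
    bivalent_allele: int = 3  # 1-based index of the duplicated allele
    n_alleles: int = 4
    clone_error_rate: float = 0.001
    n_clones_per_allele: int = 5
    individuals: tuple = ("H13", "H19", "H20")
    bud_stages: tuple = ("small", "large")
    n_gdna_replicates: int = 2
    n_cdna_replicates: int = 3
    read_depth: int = 500
    rho: float = 0.005
    expression_rates: dict | None = None  # allele label -> per-copy rate
    alpha: float = 0.05
    bh_adjust: bool = True
    seed: int = 0
    alignment_path: str | None = None  # external inputs (non-simulate mode)
    coding_mask_path: str | None = None
    frequency_table_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for key in ("alignment_path", "coding_mask_path", "frequency_table_path"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config {key} = {val!r}: file not found")
        return cfg


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)  # (stage, output file, rows)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, path: Path, rows: int) -> None:
        self.stages.append({"stage": stage, "output": path.name, "rows": rows})
        self.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def default_config(out_dir: str, seed: int = 0) -> RunConfig:
    """A simulated pentaploid single-copy locus with four alleles, the
    duplicated allele under-transcribed per copy (the LEAFY-like pattern)."""
    return RunConfig(out_dir=out_dir, seed=seed, expression_rates={"allele-3": 0.4})


def _simulate_allele_sequences(cfg: RunConfig):
    """Evolve allele coding sequences (plus an outgroup) on a star tree."""
    from .molevol.codon_model import simulate_codons

    labels = [f"allele-{i}" for i in range(1, cfg.n_alleles + 1)]
    d = cfg.allele_divergence
    tips = ",".join(f"{lab}:{d}" for lab in labels)
    tree = f"(({tips}):{2 * d},outgroup:{2 * d});"
    aln = simulate_codons(tree, omega=0.2, kappa=2.0, length=cfg.n_codons,
                          seed=cfg.seed, locus=cfg.locus)
    seqs = dict(zip(aln.names, aln.sequences))
    return labels, {lab: seqs[lab] for lab in labels}, seqs["outgroup"]


def _clone_alignment(cfg: RunConfig, labels, true_seqs) -> allele_calling.CloneAlignment:
    rng = np.random.default_rng(cfg.seed + 1)
    names, individuals, seqs = [], [], []
    bases = np.array(list("ACGT"))
    inds = list(cfg.individuals)
    for lab in labels:
        for c in range(cfg.n_clones_per_allele):
            seq = np.array(list(true_seqs[lab]))
            err = rng.random(seq.size) < cfg.clone_error_rate
            if err.any():
                seq[err] = bases[rng.integers(0, 4, size=int(err.sum()))]
            names.append(f"{lab}-clone{c + 1}")
            individuals.append(inds[c % len(inds)])
            seqs.append("".join(seq))
    L = len(seqs[0])
    return allele_calling.CloneAlignment(
        locus=cfg.locus, names=names, sequences=seqs,
        individuals=individuals, coding_mask=[(0, L)],
    )


def run_pipeline(cfg: RunConfig, simulate: bool = True) -> RunManifest:
    """Execute all stages in order; any stage failure aborts with the stage
    name, after writing the partial manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    from . import __version__

    manifest = RunManifest(tool_version=__version__, config_hash=cfg_hash, seed=cfg.seed)
    stage = "setup"
    try:
        # --- stage 1: inputs (simulated or read from disk) -----------------
        if simulate:
            stage = "simulate"
            labels, true_seqs, outgroup_seq = _simulate_allele_sequences(cfg)
            clones = _clone_alignment(cfg, labels, true_seqs)
            aln_path = out / "clones.fasta"
            cio.write_fasta_alignment(aln_path, clones.names, clones.sequences, clones.individuals)
            manifest.record("simulate", aln_path, len(clones.names))
            mask = clones.coding_mask
        else:
            stage = "read-inputs"
            if cfg.alignment_path is None or cfg.coding_mask_path is None:
                raise FileNotFoundError("non-simulate mode needs alignment_path and coding_mask_path")
            mask = cio.read_coding_mask(cfg.coding_mask_path)
            clones = cio.read_fasta_alignment(cfg.alignment_path, locus=cfg.locus, coding_mask=mask)
            outgroup_seq = None

        # --- stage 2: allele calling --------------------------------------
        stage = "callalleles"
        alleles = allele_calling.collapse_clones(clones)
        chimeras = allele_calling.detect_chimeras(clones, alleles)
        assays = allele_calling.find_diagnostic_snps(alleles, mask)
        if not assays:
            raise RuntimeError("no pyrosequencing-suitable diagnostic SNP found")
        cons_path = out / "alleles.fasta"
        cio.write_fasta_alignment(cons_path, alleles.labels,
                                  [alleles.consensi[x] for x in alleles.labels])
        manifest.record("callalleles", cons_path, len(alleles.labels))
        assay_path = out / "assays.tsv"
        cio.write_assay_table(assays, assay_path)
        manifest.record("callalleles-assays", assay_path, len(assays))
        chim_path = out / "chimeras.tsv"
        pd.DataFrame([{"clone": c.clone, "verdict": c.verdict, "score": c.score}
                      for c in chimeras]).to_csv(chim_path, sep="\t", index=False)
        manifest.record("callalleles-chimeras", chim_path, len(chimeras))

        # --- stage 3: frequency observations ------------------------------
        if simulate:
            stage = "simulate-assays"
            # map called labels to truth by consensus identity
            called_of_true = {}
            for lab in labels:
                for called, cons in alleles.consensi.items():
                    if cons == true_seqs[lab]:
                        called_of_true[lab] = called
            if len(called_of_true) < len(labels):
                manifest.warnings.append(
                    "some simulated alleles were not recovered exactly by consensus"
                )
            uni_labels = [x for x in labels if labels.index(x) + 1 != cfg.bivalent_allele]
            genotype = make_founder(
                labels[cfg.bivalent_allele - 1], tuple(uni_labels[:3]),
                [cfg.locus], ploidy=cfg.ploidy,
            )
            copies_true = genotype.copy_numbers(cfg.locus)
            copies = {called_of_true.get(k, k): v for k, v in copies_true.items()}
            rates_cfg = cfg.expression_rates or {}
            rates = {called_of_true.get(lab, lab): rates_cfg.get(lab, 1.0) for lab in labels}
            obs = simulate_experiment(
                copies,
                assays,
                AssayNoise(read_depth=cfg.read_depth, rho=cfg.rho),
                cfg.seed + 2,
                profile=ExpressionProfile(rates),
                design=ExperimentDesign(
                    individuals=tuple(cfg.individuals),
                    bud_stages=tuple(cfg.bud_stages),
                    n_gdna_replicates=cfg.n_gdna_replicates,
                    n_cdna_replicates=cfg.n_cdna_replicates,
                ),
            )
            obs_path = out / "observations.tsv"
            cio.write_frequency_table(obs, obs_path)
            manifest.record("simulate-assays", obs_path, len(obs))
        else:
            stage = "read-observations"
            if cfg.frequency_table_path is None:
                raise FileNotFoundError("non-simulate mode needs frequency_table_path")
            obs = cio.read_frequency_table(cfg.frequency_table_path)

        # --- stage 4: copy number -----------------------------------------
        stage = "copynum"
        calls = []
        for ind in sorted(obs["individual"].unique()):
            call = copy_number.infer_copy_numbers(
                obs, assays, alleles.labels, cfg.ploidy,
                noise=AssayNoise(read_depth=cfg.read_depth, rho=cfg.rho),
                individual=ind,
            )
            calls.append(call)
        call_rows = [
            {"locus": c.locus, "individual": c.individual, "allele": a, "copies": k,
             "log_likelihood": c.log_likelihood, "runner_up_gap": c.runner_up_gap}
            for c in calls for a, k in sorted(c.copies.items())
        ]
        call_path = out / "copy_numbers.tsv"
        pd.DataFrame(call_rows).to_csv(call_path, sep="\t", index=False)
        manifest.record("copynum", call_path, len(call_rows))

        # --- stage 5: allele-specific transcription ------------------------
        stage = "ase"
        results = ase.ase_report(calls, obs, assays, adjust=cfg.bh_adjust, seed=cfg.seed + 3)
        ase_path = out / "ase_results.tsv"
        ase.results_to_frame(results).to_csv(ase_path, sep="\t", index=False, na_rep=".")
        manifest.record("ase", ase_path, len(results))

        # --- stage 6: molecular evolution ----------------------------------
        stage = "dnds"
        cod_names = alleles.labels
        cod_seqs = [alleles.consensi[x] for x in cod_names]
        caln = CodonAlignment(cfg.locus, cod_names, cod_seqs)
        counts = count_substitutions(caln)
        fit = m0_fit(caln)
        pair_rows = []
        for i, a in enumerate(cod_names):
            for b in cod_names[i + 1:]:
                dn, ds, om = ng86_dnds(alleles.consensi[a], alleles.consensi[b])
                pair_rows.append({"a": a, "b": b, "dN": dn, "dS": ds,
                                  "omega": om if om is not None else "."})
        rrt_rows = []
        if outgroup_seq is not None:
            seqs = {n: alleles.consensi[n] for n in cod_names}
            seqs["outgroup"] = outgroup_seq
            for r in tajima_rrt_batch(seqs, "outgroup"):
                rrt_rows.append({"pair": "/".join(r.pair), "m1": r.m1, "m2": r.m2,
                                 "chi2": r.statistic, "p": r.p_value,
                                 "p_adjusted": r.p_adjusted, "verdict": r.verdict(cfg.alpha)})
        molevol_path = out / "molevol.tsv"
        pd.DataFrame(pair_rows).to_csv(molevol_path, sep="\t", index=False)
        manifest.record("dnds", molevol_path, len(pair_rows))
        summary = {
            "n_synonymous": counts.n_synonymous,
            "n_nonsynonymous": counts.n_nonsynonymous,
            "n_indel_events": counts.n_indel_events,
            "m0_omega": fit.omega,
            "m0_kappa": fit.kappa,
            "m0_lnL": fit.lnL,
            "rrt": rrt_rows,
        }
        sum_path = out / "molevol_summary.json"
        sum_path.write_text(json.dumps(summary, indent=2) + "\n")
        manifest.record("dnds-summary", sum_path, 1)
    except Exception as err:
        manifest.warnings.append(f"stage {stage!r} failed: {err}")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest.write(out / "manifest.json")
    return manifest
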