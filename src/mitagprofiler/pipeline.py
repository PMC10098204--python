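"""End-to-end pipeline: simulate → prep → recruit → filter → profile → pathways.

One structured config drives every stage; all randomness flows from its
single seed, and rerunning an identical config yields a byte-identical
JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import community as comm
from . import pathways as pw
from . import read_prep, recruitment, simulate
from .references import read_operons_fasta, write_operons_fasta

#: Demonstration completeness plan: which fraction of each pathway's genes
#: each dominant taxon carries, echoing the metabolic division of labour in
#: a chemolithoautotrophic lake community (acetogenesis in Acetobacterium,
#: sulphur oxidation and rTCA in the epsilonproteobacteria, dissimilatory
#: sulphate reduction in the spore-forming reducer).
DEMO_PLAN: dict[str, dict[str, float]] = {
    "Acetobacterium": {"wood_ljungdahl": 1.0, "nadp_hydrogenase": 1.0,
                       "carboxydotrophy": 1.0, "dissimilatory_sulfate_reduction": 0.5,
                       "nitrogen_fixation": 1.0},
    "Sulfuricurvum": {"reductive_tca": 0.85, "nife_hydrogenase": 1.0,
                      "assimilatory_nitrate_reduction": 1.0, "arsenate_reduction": 1.0,
                      "fumarate_respiration": 1.0, "nitrogen_fixation": 1.0},
    "Sulfurospirillum": {"reductive_tca": 0.8, "assimilatory_sulfate_reduction": 1.0,
                         "thiosulfate_reduction": 1.0, "nife_hydrogenase": 1.0,
                         "arsenate_reduction": 1.0, "nitrogen_fixation": 1.0},
    "Geobacter_Pelobacter": {"reductive_tca": 0.8, "dissimilatory_nitrate_reduction": 1.0,
                             "fumarate_respiration": 1.0, "nitrogen_fixation": 1.0},
    "Desulfosporosinus": {"dissimilatory_sulfate_reduction": 1.0},
    "Caldisericum": {"assimilatory_sulfate_reduction": 0.4},
    "Saccharibacteria": {},
    "Prolixibacteraceae": {"dissimilatory_nitrate_reduction": 0.4},
}


@dataclass
class PipelineConfig:
    """All pipeline knobs; every threshold validated against its domain."""

    seed: int = 0
    out_dir: str = "mitag_out"
    # synthetic community
    simulate_community: bool = True
    depth: float = 1000.0
    read_length: int = 108
    insert_mean: int = 175
    insert_sd: float = 15.0
    per_base_error_rate: float = 0.001
    divergence_range: tuple[float, float] = (0.83, 0.99)
    # external inputs (used when simulate_community is false)
    refs_fasta: str | None = None
    reads_r1: str | None = None
    reads_r2: str | None = None
    annotations_tsv: str | None = None
    # read prep
    min_overlap: int = 10
    max_overlap: int | None = None  # defaults to insert_mean
    max_mismatch_ratio: float = 0.25
    min_length: int = 90
    bad_fraction: float = 0.0
    quality_cutoff: int = 13
    # recruitment
    min_identity: float = 0.98
    min_coverage: float = 0.50
    # artefact test
    min_breadth: float = 0.5
    block_share: float = 0.95
    max_block_fraction: float = 0.20
    # collapsing / pathways
    significance: float = 0.95
    annotation_min_identity: float = 0.60
    presence_threshold: float = 0.80

    def validate(self) -> "PipelineConfig":
        for name in ("min_identity", "min_coverage", "significance",
                     "annotation_min_identity", "presence_threshold",
                     "min_breadth", "block_share", "max_block_fraction",
                     "max_mismatch_ratio", "bad_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_identity == 0 or self.min_coverage == 0:
            raise ValueError("recruitment thresholds must be in (0, 1]")
        lo, hi = self.divergence_range
        if not lo < hi <= 1.0:
            raise ValueError(f"invalid divergence_range {self.divergence_range}")
        if self.min_length < 1 or self.min_overlap < 1:
            raise ValueError("min_length and min_overlap must be >= 1")
        if not self.simulate_community and not (self.refs_fasta and self.reads_r1
                                                and self.reads_r2):
            raise ValueError("without simulation, refs_fasta and reads_r1/r2 are required")
        return self

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["divergence_range"] = list(self.divergence_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "divergence_range" in d:
            d["divergence_range"] = tuple(d["divergence_range"])
        return cls(**d).validate()

    def digest(self) -> str:
        """Hash of every result-affecting field (I/O locations excluded)."""
        d = asdict(self)
        d["divergence_range"] = list(self.divergence_range)
        for key in ("out_dir",):
            d.pop(key, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 6) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, log=sys.stderr) -> dict:
    """Execute every stage, write per-stage TSVs plus a JSON summary, and
    return the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def say(msg: str) -> None:
        print(f"[mitag] {msg}", file=log)

    say(f"config {config.digest()} seed {config.seed}")

    # --- inputs ------------------------------------------------------------
    if config.simulate_community:
        community_obj, refs = simulate.demo_community(config.seed,
                                                      config.divergence_range)
        sim_cfg = simulate.SimulationConfig(
            read_length=config.read_length, insert_mean=config.insert_mean,
            insert_sd=config.insert_sd,
            per_base_error_rate=config.per_base_error_rate,
            depth=config.depth, seed=config.seed,
        )
        pairs, truth = simulate.simulate_reads(community_obj, refs, sim_cfg)
        write_operons_fasta(refs, out / "references.fasta")
        truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        annotations = simulate.make_annotation_table(
            community_obj, pw.load_pathway_bundle(), DEMO_PLAN,
            seed=config.seed, n_decoys=50,
        )
        truth_fracs = community_obj.fractions
    else:
        refs = read_operons_fasta(config.refs_fasta)
        pairs = list(read_prep.read_fastq_pairs(config.reads_r1, config.reads_r2))
        annotations = (pd.read_csv(config.annotations_tsv, sep="\t")
                       if config.annotations_tsv else None)
        truth_fracs = None
    say(f"input: {len(pairs)} read pairs, {len(refs)} reference operons")

    # --- prep --------------------------------------------------------------
    merge_policy = read_prep.MergePolicy(
        config.min_overlap,
        config.max_overlap or config.insert_mean,
        config.max_mismatch_ratio,
    )
    trim_policy = read_prep.TrimPolicy(config.min_length, config.bad_fraction,
                                       config.quality_cutoff)
    cleaned, prep_stats = read_prep.prep_reads(pairs, merge_policy, trim_policy)
    read_prep.write_fastq(cleaned, out / "cleaned.fastq")
    say(f"prep: {prep_stats.summary()}")

    # --- recruitment + artefact filter -------------------------------------
    hits = recruitment.recruit(cleaned, refs, config.min_identity,
                               config.min_coverage)
    kept, homogeneity = recruitment.filter_artefacts(
        hits, refs, config.min_breadth, window=100,
        block_share=config.block_share,
        max_block_fraction=config.max_block_fraction,
    )
    pd.DataFrame([asdict(h) for h in kept]).to_csv(
        out / "hits.tsv", sep="\t", index=False)
    say(f"recruit: {len(hits)} hits, {len(hits) - len(kept)} removed as artefacts")

    # --- community profile --------------------------------------------------
    counts = recruitment.hits_to_counts(kept)
    profile = comm.normalise(counts, refs, sample_id="pipeline")
    profile.to_frame().to_csv(out / "abundance.tsv", sep="\t", index=False)
    div = comm.diversity(profile) if counts else None

    tree = comm.tree_from_profile(profile, refs)
    collapsed, moves = comm.collapse_taxonomy(tree, config.significance)
    collapsed.to_tsv(out / "collapsed_tree.tsv")

    # --- pathways -----------------------------------------------------------
    if annotations is not None and len(annotations):
        matrix = pw.call_pathways(annotations, pw.load_pathway_bundle(),
                                  config.annotation_min_identity,
                                  config.presence_threshold)
        matrix.to_csv(out / "pathway_matrix.tsv", sep="\t", index=False)
        pathway_summary = {
            f"{r.taxon_id}:{r.pathway_id}": {
                "completeness": r.completeness, "present": bool(r.present),
            }
            for r in matrix.itertuples() if r.present
        }
    else:
        pathway_summary = {}

    summary = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {
            "prep": prep_stats.summary(),
            "recruit": {
                "reads_in": prep_stats.trimmed_out,
                "hits": len(hits),
                "artefact_removed": len(hits) - len(kept),
                "unrecruited": prep_stats.trimmed_out - len(hits),
            },
        },
        "homogeneity": {
            f"{t}:{g}": {"verdict": r.verdict, "breadth": r.breadth}
            for (t, g), r in sorted(homogeneity.items())
        },
        "abundance": dict(sorted(profile.relative_abundance.items())),
        "diversity": (None if div is None else
                      {"shannon_H": div.shannon_H, "richness_S": div.richness_S,
                       "pielou_J": div.pielou_J}),
        "collapse_moves": len(moves),
        "pathways_present": pathway_summary,
    }
    if truth_fracs is not None:
        summary["truth_cell_fractions"] = truth_fracs
        summary["max_abundance_error"] = max(
            abs(profile.relative_abundance.get(t, 0.0) - f)
            for t, f in truth_fracs.items()
        )
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    say(f"done: wrote {out / 'summary.json'}")
    return summary
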