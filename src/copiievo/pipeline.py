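"""End-to-end drivers: simulate -> search -> trees -> surrogates -> counts.

Each stage draws its seed from the master seed through a fixed spawn scheme
(``numpy.random.SeedSequence(seed).spawn``), so stages can be rerun in
isolation and a rerun with the same config is bit-identical.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._scoring import ScoringScheme
from .formats import (
    PhyloTree,
    PresenceMatrix,
    SequenceRecord,
    write_fasta,
    write_presence_matrix,
)
from .phylo import Msa, bootstrap_tree, progressive_align, trim_columns
from .reconstruct import build_presence_matrix, leca_complement
from .scrollsaw import (
    AncientCladeResult,
    CladeCall,
    DEFAULT_THRESHOLDS,
    SelectionReport,
    SupergroupMap,
    assemble_pan_dataset,
    count_ancient_clades,
    find_supported_clades,
    select_surrogates,
    split_by_supergroup,
)
from .search import cascade_search
from .simulate import (
    ScaffoldConfig,
    Scenario,
    SpeciesScaffold,
    build_scaffold,
    load_scenario,
    simulate_family,
)

__all__ = [
    "RunConfig",
    "ScrollsawResult",
    "scrollsaw_analysis",
    "presence_from_search",
    "run_pipeline",
    "PipelineResult",
    "recovery_report",
    "stage_seeds",
]

_STAGES = ("simulate", "search", "align", "supergroup_trees", "pan_tree", "extra")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Per-stage 31-bit seeds derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


# ---------------------------------------------------------------------------
# scrollsaw driver
# ---------------------------------------------------------------------------

@dataclass
class ScrollsawResult:
    master: Msa
    trimmed: Msa
    reports: dict[str, SelectionReport]
    pan_msa: Msa
    pan_tree: PhyloTree
    ancient: AncientCladeResult
    seed: int


def scrollsaw_analysis(
    records: Sequence[SequenceRecord],
    sgmap: SupergroupMap | None = None,
    *,
    scheme: ScoringScheme | None = None,
    trim_gap_fraction: float = 0.5,
    thresholds: Mapping[str, float] | None = None,
    k: int = 2,
    n_boot: int = 100,
    seed: int = 0,
    metric: str = "mrca_to_tip",
    min_supergroups: int = 2,
    max_per_taxon: int | None = 1,
    outgroup_ids: Sequence[str] = (),
) -> ScrollsawResult:
    """Run the full taxon-reduction analysis on one family.

    Returns per-supergroup selection reports, the pan-eukaryotic surrogate
    alignment/tree, and the ancient-paralog count.
    """
    sgmap = sgmap or SupergroupMap.from_records(records)
    taxon_by_id = {r.id: r.taxon for r in records}

    def taxon_of(leaf_id: str) -> str:
        return taxon_by_id[leaf_id]

    master = progressive_align(records, scheme)
    trimmed = trim_columns(master, trim_gap_fraction)
    subsets = split_by_supergroup(trimmed, sgmap)

    seeds = np.random.SeedSequence(seed).spawn(len(subsets) + 1)
    reports: dict[str, SelectionReport] = {}
    for idx, sg in enumerate(sorted(subsets)):
        sub = subsets[sg]
        ids = sub.ids()
        if sub.n_rows < 4:
            # too small for a bootstrap tree: pass the whole subset through
            if sub.n_rows >= 2:
                clade = CladeCall(
                    frozenset(ids),
                    {},
                    frozenset(taxon_of(i) for i in ids),
                    frozenset({sg}),
                    surrogates=sorted(ids),
                    declared=True,
                )
                reports[sg] = SelectionReport(sg, [clade], [], None)
            else:
                reports[sg] = SelectionReport(sg, [], ids, None)
            continue
        sg_seed = int(seeds[idx].generate_state(1)[0] % (2**31))
        tree = bootstrap_tree(sub, n_reps=n_boot, seed=sg_seed)
        clades = find_supported_clades(
            tree,
            thresholds=thresholds,
            min_seqs=2,
            min_organisms=2,
            max_per_taxon=max_per_taxon,
            taxon_of=taxon_of,
            supergroup_of=sgmap.mapping,
        )
        for clade in clades:
            clade.surrogates = select_surrogates(tree, clade, k=k, metric=metric)
        placed = set().union(*(c.leaf_ids for c in clades)) if clades else set()
        reports[sg] = SelectionReport(sg, clades, sorted(set(ids) - placed), tree)

    pan = assemble_pan_dataset(list(reports.values()), trimmed, outgroup_ids)
    if pan.n_rows < 4:
        raise ValueError(f"pan-eukaryotic dataset has only {pan.n_rows} rows")
    pan_seed = int(seeds[-1].generate_state(1)[0] % (2**31))
    pan_tree = bootstrap_tree(pan, n_reps=n_boot, seed=pan_seed)
    ancient = count_ancient_clades(
        pan_tree,
        sgmap.mapping,
        thresholds=thresholds,
        min_supergroups=min_supergroups,
        max_per_taxon=max_per_taxon,
        taxon_of=taxon_of,
    )
    return ScrollsawResult(master, trimmed, reports, pan, pan_tree, ancient, seed)


# ---------------------------------------------------------------------------
# presence matrix from search verdicts
# ---------------------------------------------------------------------------

@dataclass
class _PresenceVerdict:
    is_present: bool
    evidence: str


def presence_from_search(
    records: Sequence[SequenceRecord],
    scaffold: SpeciesScaffold,
    component: str,
    *,
    scheme: ScoringScheme | None = None,
    reference_taxon: str | None = None,
    ratio_threshold: float = 1e2,
    forward_evalue_max: float = 1e-3,
) -> PresenceMatrix:
    """Presence/absence of one component across scaffold taxa by RBH search.

    The reference proteome is the (configurable) first taxon carrying the
    component; every other taxon's proteome is searched with each reference
    copy and confirmed reciprocally.
    """
    scheme = scheme or ScoringScheme()
    by_taxon: dict[str, list[SequenceRecord]] = {t: [] for t in scaffold.taxa}
    for r in records:
        by_taxon.setdefault(r.taxon, []).append(r)
    if reference_taxon is None:
        reference_taxon = next(t for t in scaffold.taxa if by_taxon[t])
    ref_proteome = by_taxon[reference_taxon]
    references = [
        (ref, ref_proteome) for ref in ref_proteome if ref.component == component
    ]
    if not references:
        raise ValueError(f"reference taxon {reference_taxon!r} has no {component} sequence")

    verdicts: dict[tuple[str, str], _PresenceVerdict] = {}
    for taxon in scaffold.taxa:
        proteome = by_taxon[taxon]
        if taxon == reference_taxon:
            verdicts[(taxon, component)] = _PresenceVerdict(bool(proteome), "declared")
            continue
        if not proteome:
            verdicts[(taxon, component)] = _PresenceVerdict(False, "rbh")
            continue
        result = cascade_search(
            proteome,
            component,
            references,
            scheme,
            forward_evalue_max=forward_evalue_max,
            ratio_threshold=ratio_threshold,
        )
        verdicts[(taxon, component)] = _PresenceVerdict(result.is_present, "rbh")
    return build_presence_matrix(verdicts, scaffold.taxa, [component])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full run needs; all thresholds in one place."""

    scenario: str = "null"
    seed: int = 0
    out_dir: str | None = None
    scaffold: ScaffoldConfig = field(default_factory=ScaffoldConfig)
    ratio_threshold: float = 1e2
    boot_min: float = 50.0
    posterior_min: float = 0.8
    trim_gap_fraction: float = 0.5
    surrogates_k: int = 2
    n_boot: int = 100
    metric: str = "mrca_to_tip"
    min_supergroups: int = 2
    run_search: bool = True

    def thresholds(self) -> dict[str, float]:
        return {"bootstrap": self.boot_min, "posterior": self.posterior_min}


@dataclass
class PipelineResult:
    config: RunConfig
    scenario: Scenario
    scaffold: SpeciesScaffold
    records: list[SequenceRecord]
    truth: object
    scrollsaw: ScrollsawResult
    presence: PresenceMatrix | None
    leca: object | None
    out_dir: Path | None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate -> (search) -> scrollsaw -> reconstruct, writing artifacts.

    The output directory receives the simulated FASTA, trimmed alignment,
    per-supergroup and pan trees (Newick with bootstrap labels), the presence
    matrix TSV, and a JSON report recording every threshold and seed used.
    """
    scenario = load_scenario(config.scenario)
    scaffold = build_scaffold(config.scaffold)
    seeds = stage_seeds(config.seed)

    records, truth = simulate_family(scaffold, scenario, seeds["simulate"])

    result = scrollsaw_analysis(
        records,
        SupergroupMap({t: scaffold.supergroup_of[t] for t in scaffold.taxa}),
        trim_gap_fraction=config.trim_gap_fraction,
        thresholds=config.thresholds(),
        k=config.surrogates_k,
        n_boot=config.n_boot,
        seed=seeds["pan_tree"],
        metric=config.metric,
        min_supergroups=config.min_supergroups,
    )

    presence = leca = None
    if config.run_search:
        presence = presence_from_search(
            records,
            scaffold,
            scenario.component,
            ratio_threshold=config.ratio_threshold,
        )
        leca = leca_complement(presence, scaffold.tree)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "family.fasta")
        write_fasta(result.trimmed.records, out_dir / "master_trimmed.afa")
        (out_dir / "pan_tree.nwk").write_text(result.pan_tree.newick() + "\n")
        for sg, report in result.reports.items():
            if report.tree is not None:
                (out_dir / f"tree_{sg}.nwk").write_text(report.tree.newick() + "\n")
        if presence is not None:
            write_presence_matrix(presence, out_dir / "presence.tsv")
        report = {
            "scenario": scenario.name,
            "seed": config.seed,
            "stage_seeds": seeds,
            "thresholds": {
                "ratio": config.ratio_threshold,
                "bootstrap": config.boot_min,
                "posterior": config.posterior_min,
                "trim_gap_fraction": config.trim_gap_fraction,
                "surrogates_k": config.surrogates_k,
                "n_boot": config.n_boot,
                "min_supergroups": config.min_supergroups,
            },
            "true_ancient_paralogs": truth.ancient_paralog_count,
            "inferred_ancient_paralogs": result.ancient.count,
            "unclassified": result.ancient.unclassified,
            "per_supergroup_clades": {
                sg: [sorted(c.leaf_ids) for c in rep.clades]
                for sg, rep in result.reports.items()
            },
            "leca_complement": list(leca.components) if leca is not None else None,
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config, scenario, scaffold, records, truth, result, presence, leca, out_dir
    )


# ---------------------------------------------------------------------------
# multi-seed recovery summaries
# ---------------------------------------------------------------------------

def recovery_report(
    scenario: str | Scenario,
    seeds: Sequence[int],
    *,
    scaffold_config: ScaffoldConfig | None = None,
    n_boot: int = 100,
    thresholds: Mapping[str, float] | None = None,
    divergence_multiplier: float = 1.0,
    supergroup_focus: str | None = None,
) -> dict:
    """Ancient-paralog recovery over replicate seeds.

    Runs simulate + scrollsaw per seed and summarizes the counts; with
    ``supergroup_focus`` the summarized statistic is instead the number of
    supported clades found in that supergroup's data set (the
    supergroup-specific view of a duplication).
    """
    scn = scenario if isinstance(scenario, Scenario) else load_scenario(scenario)
    if divergence_multiplier != 1.0:
        scn = scn.scaled(divergence_multiplier)
    scaffold = build_scaffold(scaffold_config)
    counts: list[int] = []
    truths: list[int] = []
    for seed in seeds:
        per_stage = stage_seeds(seed)
        records, truth = simulate_family(scaffold, scn, per_stage["simulate"])
        try:
            analysis = scrollsaw_analysis(
                records,
                SupergroupMap({t: scaffold.supergroup_of[t] for t in scaffold.taxa}),
                thresholds=thresholds,
                n_boot=n_boot,
                seed=per_stage["pan_tree"],
            )
        except ValueError:
            # signal too degraded for any supported structure: nothing counted
            counts.append(0)
            truths.append(truth.ancient_paralog_count)
            continue
        if supergroup_focus is not None:
            counts.append(len(analysis.reports[supergroup_focus].clades))
        else:
            counts.append(analysis.ancient.count)
        truths.append(truth.ancient_paralog_count)
    modal = Counter(counts).most_common(1)[0][0]
    true_count = truths[0]
    return {
        "scenario": scn.name,
        "counts": counts,
        "modal_count": modal,
        "true_count": true_count,
        "recovery_rate": sum(1 for c in counts if c == true_count) / len(counts),
        "n_seeds": len(seeds),
    }
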