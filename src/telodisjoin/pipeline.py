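"""Scenario orchestration: configuration, seed splitting, end-to-end runs.

A scenario builds the toy genome pair once, then for each condition runs
the requested simulators and analyses (ChIP calibration, Hi-C telomere
aggregation, foci scoring), compares every condition against the control,
and writes a manifest with derived seeds and file checksums. Child seeds
are derived by hashing (master seed, stage name) so stages never share a
random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import chip, foci, hic, simulate
from .genome import (
    GenomeConfig,
    GenomeModel,
    build_toy_genome,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)

__all__ = [
    "AnalysisConfig",
    "ConditionConfig",
    "ScenarioConfig",
    "ScenarioResult",
    "child_seed",
    "run_scenario",
    "preset_scenario",
    "hic_genome_config",
    "chip_recovery_trial",
    "hic_discrimination_trial",
]

logger = logging.getLogger(__name__)


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed by hashing (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") >> 1  # non-negative 63-bit


@dataclass
class AnalysisConfig:
    mixing_ratio: float = 5.0
    bin_size: int = 1
    pseudocount: float = 1.0
    total_floor: float = 5.0
    region_bp: int = 150_000
    window: int = 21
    step: int = 1
    merge_radius: float = 0.3
    stage_thresholds: tuple[float, float] = (4.0, 5.0)
    alpha: float = 0.001


@dataclass
class ConditionConfig:
    chip: simulate.EnrichmentProfile | None = None
    hic: simulate.HiCSimParams | None = None
    mitotic: simulate.MitoticSimParams | None = None

    def validate(self) -> None:
        if self.chip is not None:
            self.chip.validate()
        if self.hic is not None:
            self.hic.validate()
        if self.mitotic is not None:
            self.mitotic.validate()


@dataclass
class ScenarioConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    conditions: dict[str, ConditionConfig] = field(default_factory=dict)
    control: str = "wildtype"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    master_seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("scenario has no conditions")
        if self.control not in self.conditions:
            raise ValueError(f"control condition {self.control!r} not defined")
        for cond in self.conditions.values():
            cond.validate()

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(_plain(self.to_dict()), handle, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        genome = _genome_config(raw.get("genome", {}))
        analysis = AnalysisConfig(**_tupled(raw.get("analysis", {}), ("stage_thresholds",)))
        conditions = {}
        for name, cond in raw.get("conditions", {}).items():
            conditions[name] = ConditionConfig(
                chip=_profile(cond.get("chip")),
                hic=_hic_params(cond.get("hic")),
                mitotic=_mitotic_params(cond.get("mitotic")),
            )
        return cls(
            genome=genome,
            conditions=conditions,
            control=raw.get("control", "wildtype"),
            analysis=analysis,
            master_seed=int(raw.get("master_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


def _plain(obj: Any) -> Any:
    """Make a nested structure YAML/JSON-safe (tuples -> lists, numpy -> py)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _tupled(raw: dict, keys: tuple[str, ...]) -> dict:
    out = dict(raw)
    for key in keys:
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    return out


def _genome_config(raw: dict) -> GenomeConfig:
    raw = _tupled(raw, ("chromosome_lengths", "chromosome_names"))
    if "ste_blocks" in raw:
        raw["ste_blocks"] = tuple((str(n), int(s)) for n, s in raw["ste_blocks"])
    return GenomeConfig(**raw)


def _profile(raw: dict | None) -> simulate.EnrichmentProfile | None:
    if raw is None:
        return None
    return simulate.EnrichmentProfile(**raw)


def _hic_params(raw: dict | None) -> simulate.HiCSimParams | None:
    if raw is None:
        return None
    return simulate.HiCSimParams(**raw)


def _mitotic_params(raw: dict | None) -> simulate.MitoticSimParams | None:
    if raw is None:
        return None
    raw = _tupled(raw, ("stage_mix", "interphase_clusters"))
    if "spb_distance" in raw:
        raw["spb_distance"] = {k: tuple(v) for k, v in raw["spb_distance"].items()}
    return simulate.MitoticSimParams(**raw)


# ---------------------------------------------------------------------------
# reusable analysis trials (also exercised by the acceptance suite)
# ---------------------------------------------------------------------------


def hic_genome_config(**overrides) -> GenomeConfig:
    """Genome layout suited to 150-kb end regions at 5 kb: unequal
    chromosome lengths so extreme diagonals are not dominated by telomere
    corners."""
    defaults = dict(
        chromosome_lengths=(500_000, 600_000, 700_000),
        genes_per_chromosome=20,
    )
    defaults.update(overrides)
    return GenomeConfig(**defaults)


def chip_recovery_trial(
    seed: int,
    genome_pair: tuple[GenomeModel, GenomeModel] | None = None,
    profile: simulate.EnrichmentProfile | None = None,
    mixing_ratio: float = 5.0,
    pseudocount: float = 1.0,
    total_floor: float = 5.0,
) -> dict:
    """Simulate ChIP and recover the planted telomere fold.

    Returns the calibration factor, the recovered telomere fold from the
    calibrated ratio, the uncalibrated fold, and the tracks.
    """
    target, spikein = genome_pair or build_toy_genome()
    profile = profile or simulate.EnrichmentProfile()
    sim = simulate.simulate_chip(target, spikein, profile, mixing_ratio, seed)
    cov = {
        key: chip.coverage_from_fragments(
            frags,
            target if key[1] == "target" else spikein,
            species=key[1],
            fraction=key[0],
        )
        for key, frags in sim.fragments.items()
    }
    alpha = chip.calibration_factor(cov[("IP", "spikein")], cov[("Total", "spikein")])
    ratio = chip.calibrated_ratio(
        cov[("IP", "target")], cov[("Total", "target")],
        alpha, pseudocount, total_floor=total_floor,
    )
    raw_ratio = chip.uncalibrated_ratio(
        cov[("IP", "target")], cov[("Total", "target")],
        pseudocount, total_floor=total_floor,
    )
    return {
        "alpha": alpha,
        "fold": chip.telomere_fold(ratio, target),
        "calibrated_mean": float(np.nanmean(ratio.unmasked_values())),
        "uncalibrated_mean": float(np.nanmean(raw_ratio.unmasked_values())),
        "ratio": ratio,
        "uncalibrated": raw_ratio,
        "coverage": cov,
        "simulation": sim,
    }


def hic_discrimination_trial(
    seed: int,
    genome: GenomeModel | None = None,
    wt_params: simulate.HiCSimParams | None = None,
    mut_params: simulate.HiCSimParams | None = None,
    region_bp: int = 150_000,
    window: int = 21,
    step: int = 1,
    alpha: float = 0.001,
) -> dict[str, hic.ComparisonResult]:
    """One wild-type-like vs mutant-like Hi-C discrimination trial.

    Simulates both conditions, normalizes (VC_SQRT then observed/expected),
    aggregates telomere and centromere pairs, and compares mutant vs
    wild-type per class. Returns {"intra", "inter", "cen"} comparisons with
    the mutant as condition a.
    """
    if genome is None:
        genome, _ = build_toy_genome(hic_genome_config())
    wt_params = wt_params or simulate.wildtype_hic_params()
    mut_params = mut_params or simulate.cut14_hic_params()

    results: dict[str, hic.ComparisonResult] = {}
    stacks = {}
    for label, params, child in (
        ("wt", wt_params, child_seed(seed, "hic:wt")),
        ("mut", mut_params, child_seed(seed, "hic:mut")),
    ):
        m = simulate.simulate_hic(genome, params, seed=child, condition=label)
        oe = hic.observed_over_expected(hic.vc_sqrt_normalize(m))
        tel, _excluded = hic.telomere_aggregate(oe, genome, region_bp, window, step)
        cen = hic.centromere_aggregate(oe, genome, region_bp, window, step)
        stacks[label] = {"intra": tel["intra"], "inter": tel["inter"], "cen": cen}
    for pair_class in ("intra", "inter", "cen"):
        results[pair_class] = hic.compare_conditions(
            stacks["mut"][pair_class], stacks["wt"][pair_class], alpha=alpha
        )
    return results


# ---------------------------------------------------------------------------
# full scenario runs
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    summary: dict
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(_plain(obj), indent=2, sort_keys=True) + "\n")


def preset_scenario(name: str = "wt_vs_cut14", master_seed: int = 0) -> ScenarioConfig:
    """Built-in scenario presets.

    ``wt_vs_cut14``: condensin-mutant-like Hi-C/foci parameters against a
    wild-type-like control. ``taz1``: ChIP preset with the telomere
    multiplier halved.
    """
    if name == "wt_vs_cut14":
        conditions = {
            "wildtype": ConditionConfig(
                chip=simulate.wildtype_chip_profile(),
                hic=simulate.wildtype_hic_params(),
                mitotic=simulate.MitoticSimParams(disjunction_prob=0.95),
            ),
            "cut14": ConditionConfig(
                chip=simulate.wildtype_chip_profile(),
                hic=simulate.cut14_hic_params(),
                mitotic=simulate.MitoticSimParams(disjunction_prob=0.1),
            ),
        }
        return ScenarioConfig(
            genome=hic_genome_config(),
            conditions=conditions,
            control="wildtype",
            master_seed=master_seed,
        )
    if name == "taz1":
        conditions = {
            "wildtype": ConditionConfig(chip=simulate.wildtype_chip_profile()),
            "taz1": ConditionConfig(chip=simulate.taz1_chip_profile()),
        }
        return ScenarioConfig(
            conditions=conditions, control="wildtype", master_seed=master_seed
        )
    raise ValueError(f"unknown preset {name!r}")


def run_scenario(config: ScenarioConfig, out_dir: str | Path) -> ScenarioResult:
    """Run sim -> chip -> hic -> foci -> stats for every condition.

    Writes all intermediates under ``out_dir`` (genome/, <condition>/chip,
    <condition>/hic, <condition>/foci, report/) plus a manifest recording
    the configuration, derived child seeds, and a checksum per output file.
    Any stage failure raises with the stage and condition identified.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    seeds: dict[str, int] = {}
    files: list[Path] = []
    summary: dict[str, Any] = {"conditions": {}, "comparisons": {}}

    def stage_seed(stage: str) -> int:
        seeds[stage] = child_seed(config.master_seed, stage)
        return seeds[stage]

    # genome
    genome_dir = out_dir / "genome"
    genome_dir.mkdir(exist_ok=True)
    try:
        target, spikein = build_toy_genome(config.genome)
    except Exception as exc:
        raise RuntimeError(f"stage genome failed: {exc}") from exc
    for g, tag in ((target, "target"), (spikein, "spikein")):
        write_fasta(g, genome_dir / f"{tag}.fa")
        write_bed(g.features, genome_dir / f"{tag}.bed")
        write_chrom_sizes(g, genome_dir / f"{tag}.chrom.sizes")
        files += [genome_dir / f"{tag}.fa", genome_dir / f"{tag}.bed",
                  genome_dir / f"{tag}.chrom.sizes"]

    oe_stacks: dict[str, dict] = {}
    for name, cond in config.conditions.items():
        cond_summary: dict[str, Any] = {}
        cdir = out_dir / name
        if cond.chip is not None:
            try:
                trial = chip_recovery_trial(
                    stage_seed(f"chip:{name}"),
                    genome_pair=(target, spikein),
                    profile=cond.chip,
                    mixing_ratio=ana.mixing_ratio,
                    pseudocount=ana.pseudocount,
                    total_floor=ana.total_floor,
                )
            except Exception as exc:
                raise RuntimeError(f"stage chip failed for {name!r}: {exc}") from exc
            (cdir / "chip").mkdir(parents=True, exist_ok=True)
            chip.write_bedgraph(trial["ratio"], cdir / "chip" / "ratio.bedgraph")
            files.append(cdir / "chip" / "ratio.bedgraph")
            cond_summary["chip"] = {
                "alpha": trial["alpha"],
                "telomere_fold": trial["fold"],
            }
        if cond.hic is not None:
            try:
                m = simulate.simulate_hic(
                    target, cond.hic, seed=stage_seed(f"hic:{name}"), condition=name
                )
                oe = hic.observed_over_expected(hic.vc_sqrt_normalize(m))
                tel, excluded = hic.telomere_aggregate(
                    oe, target, ana.region_bp, ana.window, ana.step
                )
                cen = hic.centromere_aggregate(
                    oe, target, ana.region_bp, ana.window, ana.step
                )
            except Exception as exc:
                raise RuntimeError(f"stage hic failed for {name!r}: {exc}") from exc
            (cdir / "hic").mkdir(parents=True, exist_ok=True)
            hic.write_matrix_tsv(oe, cdir / "hic" / "oe.tsv")
            files.append(cdir / "hic" / "oe.tsv")
            oe_stacks[name] = {"intra": tel["intra"], "inter": tel["inter"], "cen": cen}
            cond_summary["hic"] = {
                cls: stack.score() for cls, stack in oe_stacks[name].items()
            }
            cond_summary["hic"]["excluded_pairs"] = len(excluded)
        if cond.mitotic is not None:
            try:
                cells = simulate.simulate_mitotic_cells(
                    target, cond.mitotic, seed=stage_seed(f"cells:{name}"),
                    condition=name,
                )
                profile = foci.disjunction_profile(
                    cells,
                    n_chromosomes=len(target.chromosomes),
                    merge_radius=ana.merge_radius,
                    thresholds=ana.stage_thresholds,
                )
            except Exception as exc:
                raise RuntimeError(f"stage foci failed for {name!r}: {exc}") from exc
            (cdir / "foci").mkdir(parents=True, exist_ok=True)
            foci.write_cells(cells, cdir / "foci" / "cells.tsv")
            profile.per_cell.to_csv(cdir / "foci" / "per_cell.tsv", sep="\t", index=False)
            files += [cdir / "foci" / "cells.tsv", cdir / "foci" / "per_cell.tsv"]
            cond_summary["foci"] = profile.summary
        summary["conditions"][name] = cond_summary

    # condition-vs-control Hi-C comparisons
    if config.control in oe_stacks:
        for name in oe_stacks:
            if name == config.control:
                continue
            comp = {}
            for cls in ("intra", "inter", "cen"):
                result = hic.compare_conditions(
                    oe_stacks[name][cls], oe_stacks[config.control][cls],
                    alpha=ana.alpha,
                )
                comp[cls] = {
                    "score_condition": result.score_a,
                    "score_control": result.score_b,
                    "p_raw": result.raw_test.p_value,
                    "p_quantized": result.quantized_test.p_value,
                    "significant_raw": result.significant_raw,
                    "significant_quantized": result.significant_quantized,
                }
            summary["comparisons"][name] = comp

    report_dir = out_dir / "report"
    report_dir.mkdir(exist_ok=True)
    _write_json(summary, report_dir / "summary.json")
    files.append(report_dir / "summary.json")

    manifest = {
        "config": _plain(config.to_dict()),
        "seeds": seeds,
        "checksums": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)
        },
    }
    _write_json(manifest, out_dir / "manifest.json")
    return ScenarioResult(summary=summary, manifest=manifest, out_dir=out_dir)
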