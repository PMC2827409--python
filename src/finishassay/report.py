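"""Per-BAC aggregation into per-species / per-region reports, and the
end-to-end synthetic pipeline.

The pipeline wires the stages together for a simulated cohort: generate a
reference, simulate biased shotgun pairs, derive the draft, realign the
(shuffled) contigs, resolve the contig map, call and classify gaps, profile
redundancy, and aggregate.  A conservation identity (placed contig bases +
internal gap bases + terminal gap bases == finished length) is checked per
BAC and the run fails loudly on violation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .capture import classify_gaps, uncaptured_burden
from .composition import composition_ci, gap_composition_profiles, flatten_annotation
from .coverage import depth_profile, variation_score
from .gaps import call_gaps, gap_stats
from .mapping import align_contigs, resolve_map
from .model import (
    BacResult,
    BiasModel,
    BiasRegion,
    CaptureRule,
    Gap,
    SCORE_LEVELS,
)
from .synthetic import (
    GCIslandConfig,
    RandomRepeats,
    RepeatConfig,
    build_draft,
    generate_reference,
    simulate_shotgun,
)

__all__ = [
    "aggregate_manifest",
    "load_manifest",
    "summarize",
    "CohortConfig",
    "run_pipeline",
    "analyze_bac",
]

log = logging.getLogger("finishassay")


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "bac_id" not in df.columns and "n_bacs" not in df.columns:
        raise ValueError("manifest needs a bac_id or n_bacs column")
    return df


def aggregate_manifest(rows: pd.DataFrame | Sequence[Mapping]) -> tuple[int, float]:
    """Totals (n_bacs, total_mb) over manifest rows.

    Rows are per-BAC (each counts 1) unless an ``n_bacs`` column gives
    per-row counts (per-species summary tables).  ``total_mb`` comes from a
    ``total_mb`` column or from ``finished_length`` in bp.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("manifest is empty")
    if "bac_id" in df.columns and df["bac_id"].duplicated().any():
        dups = df.loc[df["bac_id"].duplicated(), "bac_id"].tolist()
        raise ValueError(f"duplicate bac_id: {dups}")
    n = int(df["n_bacs"].sum()) if "n_bacs" in df.columns else len(df)
    if "total_mb" in df.columns:
        mb = float(df["total_mb"].sum())
    elif "finished_length" in df.columns:
        mb = float(df["finished_length"].sum()) / 1e6
    else:
        raise ValueError("manifest needs total_mb or finished_length")
    return n, mb


_SCORE_VALUE = {s: i for i, s in enumerate(SCORE_LEVELS)}


def summarize(
    units: Sequence[BacResult],
    group_by: str = "species",
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One report row per group with gap statistics and capture burden.

    Captured/uncaptured per-Mb rates carry percentile-bootstrap 95% CIs
    resampling BACs within the group.  All internal gaps must be classified.
    """
    if group_by not in ("species", "region"):
        raise ValueError("group_by must be species or region")
    groups: dict[str, list[BacResult]] = {}
    for b in units:
        groups.setdefault(getattr(b, group_by), []).append(b)
    rows = []
    for name in sorted(groups):
        bacs = groups[name]
        if not bacs:
            log.warning("empty group %s omitted", name)
            continue
        internal = [g for b in bacs for g in b.gaps if g.kind == "internal"]
        if any(g.status == "unset" for g in internal):
            raise ValueError(f"group {name}: unclassified internal gaps")
        total_mb = sum(b.finished_length for b in bacs) / 1e6
        stats = gap_stats(internal, total_mb, unit=name)
        mbs = [b.finished_length / 1e6 for b in bacs]
        # alternative normalization: per Mb of contig-aligned (placed)
        # reference, alongside the per-finished-Mb headline rate
        aligned_mb = sum(
            b.finished_length - sum(g.size for g in b.gaps) for b in bacs
        ) / 1e6

        def per_mb_ci(status: str) -> tuple[float, float | None, float | None]:
            rates = [
                sum(g.status == status for g in b.gaps if g.kind == "internal") / mb
                for b, mb in zip(bacs, mbs)
            ]
            return composition_ci(rates, mbs, reps=reps, seed=seed)

        cap, cap_lo, cap_hi = per_mb_ci("captured")
        unc, unc_lo, unc_hi = per_mb_ci("uncaptured")
        n_unc = sum(g.status == "uncaptured" for g in internal)
        multi = sum(
            sum(g.status == "uncaptured" for g in b.gaps if g.kind == "internal") >= 2
            for b in bacs
        )
        scores = [b.redundancy_score for b in bacs if b.redundancy_score]
        rows.append(
            {
                group_by: name,
                "n_bacs": len(bacs),
                "total_mb": total_mb,
                "n_gaps": stats.n_gaps,
                "gaps_per_mb": stats.gaps_per_mb,
                "gaps_per_aligned_mb": (
                    stats.n_gaps / aligned_mb if aligned_mb > 0 else float("nan")
                ),
                "gap_bases_per_mb": stats.gap_bases_per_mb,
                "median_gap_size": stats.median_gap_size,
                "captured_per_mb": cap,
                "captured_per_mb_lo": cap_lo,
                "captured_per_mb_hi": cap_hi,
                "uncaptured_per_mb": unc,
                "uncaptured_per_mb_lo": unc_lo,
                "uncaptured_per_mb_hi": unc_hi,
                "frac_gaps_uncaptured": n_unc / len(internal) if internal else 0.0,
                "frac_assemblies_ge2_uncaptured": multi / len(bacs),
                "mean_redundancy_score": (
                    float(np.mean([_SCORE_VALUE[s] for s in scores]))
                    if scores
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortConfig:
    """Study conditions for a simulated BAC cohort.

    Defaults emulate the source data: ~165 kb BACs, 8-fold read redundancy
    from 3-5 kb plasmid subclones (mean 4,000 bp, sd 400 bp), 800 bp reads,
    contigs retained above 2 kb, and a few kb-scale clone-viability troughs
    per BAC producing the observed handful of gaps.
    """

    n_bacs: int = 8
    length: int = 165_000
    gc_target: float = 0.41
    redundancy: float = 8.0
    read_len: int = 800
    insert_mean: float = 4000.0
    insert_sd: float = 400.0
    min_contig: int = 2000
    host: str = "standard"
    copy_control_rescue: float = 1.0
    n_bias_regions: int = 3
    bias_region_length: int = 2500
    bias_viability: float = 0.1
    #: interspersed + simple repeat content per BAC
    n_line: int = 10
    line_length: int = 4000
    n_sine: int = 40
    sine_length: int = 300
    n_ltr: int = 6
    ltr_length: int = 1500
    n_dna: int = 6
    dna_length: int = 800
    n_simple: int = 30
    simple_length: int = 60
    simple_in_bias_fraction: float = 0.0
    n_gc_islands: int = 2
    gc_island_length: int = 2100
    gc_island_gc: float = 0.8
    shuffle_contigs: bool = True
    species: tuple[str, ...] = ("speciesA",)
    regions: tuple[str, ...] = ("ENs001",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("species", "regions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["species"] = list(data["species"])
        data["regions"] = list(data["regions"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def repeat_config(self) -> RepeatConfig:
        random = []
        for cls_name, count, mean in (
            ("LINE", self.n_line, self.line_length),
            ("SINE", self.n_sine, self.sine_length),
            ("LTR", self.n_ltr, self.ltr_length),
            ("DNA", self.n_dna, self.dna_length),
        ):
            if count:
                random.append(
                    RandomRepeats(cls_name, count, mean, mean * 0.25)
                )
        if self.n_simple:
            random.append(
                RandomRepeats(
                    "Simple",
                    self.n_simple,
                    self.simple_length,
                    self.simple_length * 0.25,
                    in_bias_fraction=self.simple_in_bias_fraction,
                )
            )
        return RepeatConfig(random=tuple(random))

    def island_config(self) -> GCIslandConfig:
        return GCIslandConfig(
            count=self.n_gc_islands,
            length=self.gc_island_length,
            gc=self.gc_island_gc,
        )

    def draw_bias(self, rng: np.random.Generator) -> BiasModel:
        regions = []
        occupied: list[tuple[int, int]] = []
        for _ in range(self.n_bias_regions):
            for _ in range(100):
                s = int(rng.integers(0, self.length - self.bias_region_length))
                e = s + self.bias_region_length
                if all(e <= a or s >= b for a, b in occupied):
                    occupied.append((s, e))
                    regions.append(BiasRegion(s, e, self.bias_viability))
                    break
        regions.sort()
        return BiasModel(regions, self.host, self.copy_control_rescue)


def analyze_bac(
    config: CohortConfig,
    seed: int,
    bac_id: str = "bac",
    species: str = "synthetic",
    region: str = "synthetic",
    rule: CaptureRule | None = None,
):
    """Simulate and analyze one BAC end-to-end.

    Returns ``(BacResult, truth, extras)`` where ``extras`` carries the
    intermediate objects (reference, annotation, pairs, draft, map,
    composition profiles) for downstream reporting.
    """
    rng = np.random.default_rng(seed)
    bias = config.draw_bias(rng)
    ref, ann = generate_reference(
        config.length,
        config.gc_target,
        config.repeat_config(),
        config.island_config(),
        seed=int(rng.integers(2**31)),
        sequence_id=bac_id,
        species=species,
        region=region,
        bias=bias,
    )
    pairs = simulate_shotgun(
        ref,
        config.redundancy,
        config.read_len,
        config.insert_mean,
        config.insert_sd,
        bias,
        seed=int(rng.integers(2**31)),
    )
    draft, truth = build_draft(
        ref,
        pairs,
        config.min_contig,
        shuffle=config.shuffle_contigs,
        bias=bias,
        annotation=ann,
        seed=int(rng.integers(2**31)),
    )
    alignments = align_contigs(draft.contigs, ref)
    cmap = resolve_map(
        alignments,
        ref.length,
        sequence_id=ref.id,
        all_contig_ids=[c.id for c in draft.contigs],
    )
    gaps = call_gaps(cmap, ref.length)
    gaps = classify_gaps(
        gaps, pairs, rule or CaptureRule(), config.insert_mean, config.insert_sd
    )

    # Conservation identity: placed + gap + terminal bases == finished length.
    placed = sum(p.ref_span for p in cmap.placements)
    gap_bases = sum(g.size for g in gaps)
    if placed + gap_bases != ref.length:
        raise AssertionError(
            f"{bac_id}: conservation violated "
            f"({placed} placed + {gap_bases} gap != {ref.length})"
        )

    profile = depth_profile(
        [p.fwd for p in pairs] + [p.rev for p in pairs], ref.length, ref.id
    )
    score = variation_score(profile)
    result = BacResult(
        bac_id=bac_id,
        species=species,
        region=region,
        finished_length=ref.length,
        gaps=gaps,
        redundancy_score=score,
        summary_cv=profile.summary_cv,
    )
    composition = gap_composition_profiles(ref, ann, gaps, unit=bac_id)
    extras = {
        "reference": ref,
        "annotation": ann,
        "bias": bias,
        "pairs": pairs,
        "draft": draft,
        "truth": truth,
        "map": cmap,
        "profile": profile,
        "composition": composition,
    }
    return result, truth, extras


def run_pipeline(
    config: CohortConfig,
    seed: int = 0,
    outdir: str | Path | None = None,
    rule: CaptureRule | None = None,
) -> dict:
    """Run the full assay over a simulated cohort.

    BAC seeds are drawn deterministically from ``seed``.  When ``outdir`` is
    given the interchange files (gaps.bed / gaps.tsv / composition.tsv /
    summary_by_species.tsv / summary_by_region.tsv / run.log) are written.
    """
    rng = np.random.default_rng(seed)
    bac_seeds = [int(s) for s in rng.integers(2**31, size=config.n_bacs)]
    results: list[BacResult] = []
    truths = []
    comp_rows = []
    all_gaps: list[Gap] = []
    for i, bac_seed in enumerate(bac_seeds):
        species = config.species[i % len(config.species)]
        region = config.regions[i % len(config.regions)]
        bac_id = f"bac{i:03d}"
        result, truth, extras = analyze_bac(
            config, bac_seed, bac_id, species, region, rule
        )
        log.info(
            "%s: %d contigs, %d internal gaps (%d uncaptured), score %s",
            bac_id,
            len(extras["map"].placements),
            sum(g.kind == "internal" for g in result.gaps),
            sum(g.status == "uncaptured" for g in result.gaps),
            result.redundancy_score,
        )
        results.append(result)
        truths.append(truth)
        all_gaps.extend(result.gaps)
        for scope, prof in extras["composition"].items():
            row = {
                "bac_id": bac_id,
                "species": species,
                "region": region,
                "scope": scope,
                "n_bases": prof.n_bases,
                "gc": prof.gc,
            }
            for cls_name, (frac, _, _) in prof.repeat_fraction.items():
                row[f"frac_{cls_name}"] = frac
            comp_rows.append(row)

    by_species = summarize(results, "species", seed=seed)
    by_region = summarize(results, "region", seed=seed)
    composition = pd.DataFrame(comp_rows)

    out = {
        "results": results,
        "truths": truths,
        "summary_by_species": by_species,
        "summary_by_region": by_region,
        "composition": composition,
        "gaps": all_gaps,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_gaps_bed(outdir / "gaps.bed", all_gaps)
        fio.write_gaps_tsv(outdir / "gaps.tsv", all_gaps)
        composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        _write_rounded(by_species, outdir / "summary_by_species.tsv")
        _write_rounded(by_region, outdir / "summary_by_region.tsv")
        by_species.to_csv(outdir / "summary_by_species_full.tsv", sep="\t", index=False)
        by_region.to_csv(outdir / "summary_by_region_full.tsv", sep="\t", index=False)
        with open(outdir / "run.log", "w") as fh:
            fh.write(
                f"seed={seed} n_bacs={config.n_bacs} length={config.length} "
                f"redundancy={config.redundancy} host={config.host}\n"
            )
            for r in results:
                fh.write(
                    f"{r.bac_id}\t{r.species}\t{r.region}\t"
                    f"{sum(g.kind == 'internal' for g in r.gaps)} internal gaps\t"
                    f"score {r.redundancy_score}\n"
                )
    return out


def _write_rounded(df: pd.DataFrame, path: Path) -> None:
    """Report file at presentation precision (one decimal for rates)."""
    rounded = df.copy()
    for col in rounded.columns:
        if rounded[col].dtype.kind == "f":
            rounded[col] = rounded[col].round(1)
    rounded.to_csv(path, sep="\t", index=False)
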