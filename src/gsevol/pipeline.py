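"""End-to-end orchestration: simulate -> annotate -> date -> metrics -> correlate.

Every stage reads and writes plain files (FASTA / GFF3 / TSV / Newick), so
any stage can be re-run standalone or replaced by an external tool's output
with the same schema.  A completed stage leaves a marker recording the
config hash; re-running with the same config and seed skips finished stages
and reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    RepeatLibrary,
    compute_class_proportions,
    find_ltr_candidates,
    find_tandem_repeats,
    ltr_elements_to_annotations,
    mask_with_library,
    resolve_overlaps,
)
from .comparative import read_newick, results_to_frame, run_correlation_suite
from .dating import (
    DatingParams,
    date_elements,
    read_elements_tsv,
    species_mean_insertion_time,
    write_elements_tsv,
)
from .elements import LTRElement
from .genome import read_fasta, write_fasta
from .gffio import read_gff3, write_bed, write_gff3
from .metrics import ANCESTRAL_MB, assemble_species_table, read_ploidy_table
from .simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_yule_tree,
    write_library_fasta,
    write_truth_gff,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "annotate", "date", "metrics", "correlate")


@dataclass
class PanelConfig:
    """Synthetic species panel: one genome per species, sizes and LTR loads varied.

    Per-species genome length and LTR count are drawn uniformly from the
    given ranges so that genome size and LTR content vary across the panel;
    the Yule tree supplies the phylogeny and m/n counts are drawn at random
    (polyploidy is a per-species integer input, not a sequence event).
    """

    n_species: int = 5
    genome_length_range: tuple[int, int] = (150_000, 400_000)
    n_ltr_range: tuple[int, int] = (5, 30)
    birth_rate: float = 1.0
    base: SimulationConfig = field(default_factory=SimulationConfig)


@dataclass
class PipelineConfig:
    """One reproducible run: either real input paths or a simulation block."""

    outdir: str
    seed: int = 0
    # real inputs (all four required together)
    genomes_dir: str | None = None
    library_fasta: str | None = None
    tree_newick: str | None = None
    ploidy_tsv: str | None = None
    # simulation block
    panel: PanelConfig | None = None
    # stage thresholds
    tandem: dict = field(default_factory=dict)
    mask: dict = field(default_factory=dict)
    ltr: dict = field(default_factory=dict)
    dating: DatingParams = field(default_factory=DatingParams)
    ancestral_mb: float = ANCESTRAL_MB

    def __post_init__(self) -> None:
        real = all(
            x is not None
            for x in (self.genomes_dir, self.library_fasta, self.tree_newick, self.ploidy_tsv)
        )
        if real == (self.panel is not None):
            raise ValueError(
                "exactly one of {real input paths, simulation panel} must be set"
            )
        self.simulated = not real

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "panel" in raw and raw["panel"] is not None:
            panel = raw["panel"]
            if "base" in panel and panel["base"] is not None:
                panel["base"] = SimulationConfig(**panel["base"])
            for key in ("genome_length_range", "n_ltr_range"):
                if key in panel:
                    panel[key] = tuple(panel[key])
            raw["panel"] = PanelConfig(**panel)
        if "dating" in raw and raw["dating"] is not None:
            raw["dating"] = DatingParams(**raw["dating"])
        return cls(**raw)


@dataclass
class RunReport:
    """Outputs of one pipeline run plus provenance."""

    factor_table: pd.DataFrame
    regression_table: pd.DataFrame
    provenance: dict


def _marker(out: Path, stage: str) -> Path:
    return out / f".stage_{stage}.done"


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(out, stage)
    return m.exists() and m.read_text().strip() == cfg_hash


def _mark_done(out: Path, stage: str, cfg_hash: str) -> None:
    _marker(out, stage).write_text(cfg_hash + "\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, resuming past completed ones."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    t0 = time.time()

    if config.simulated:
        if not _stage_done(out, "simulate", cfg_hash):
            _run_simulate(config, out)
            _mark_done(out, "simulate", cfg_hash)
        genomes_dir = out / "genomes"
        library_fasta = out / "library.fasta"
        tree_newick = out / "tree.nwk"
        ploidy_tsv = out / "ploidy.tsv"
    else:
        genomes_dir = Path(config.genomes_dir)
        library_fasta = Path(config.library_fasta)
        tree_newick = Path(config.tree_newick)
        ploidy_tsv = Path(config.ploidy_tsv)

    species = sorted(p.stem for p in genomes_dir.glob("*.fasta"))
    if not species:
        raise FileNotFoundError(f"no *.fasta genomes under {genomes_dir}")

    if not _stage_done(out, "annotate", cfg_hash):
        _run_annotate(config, out, genomes_dir, library_fasta, species)
        _mark_done(out, "annotate", cfg_hash)
    if not _stage_done(out, "date", cfg_hash):
        _run_date(config, out, genomes_dir, species)
        _mark_done(out, "date", cfg_hash)
    if not _stage_done(out, "metrics", cfg_hash):
        _run_metrics(config, out, genomes_dir, ploidy_tsv, species)
        _mark_done(out, "metrics", cfg_hash)
    if not _stage_done(out, "correlate", cfg_hash):
        _run_correlate(config, out, tree_newick)
        _mark_done(out, "correlate", cfg_hash)

    factor_table = pd.read_csv(out / "species_factors.tsv", sep="\t")
    regression_table = pd.read_csv(out / "regressions.tsv", sep="\t")
    provenance = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_species": len(species),
    }
    report = RunReport(factor_table, regression_table, provenance)
    (out / "report.json").write_text(
        json.dumps(
            {
                "provenance": provenance,
                "factors": factor_table.to_dict(orient="records"),
                "regressions": regression_table.to_dict(orient="records"),
            },
            indent=2,
            default=str,
        )
    )
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_simulate(config: PipelineConfig, out: Path) -> None:
    panel = config.panel
    rng = np.random.default_rng(config.seed)
    (out / "genomes").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    tree = simulate_yule_tree(panel.n_species, panel.birth_rate, rng)
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]

    from .simulate import make_decoy_library

    library = make_decoy_library(panel.base, rng)  # shared across the panel
    ploidy_rows = []
    for i, sp in enumerate(species):
        cfg = dataclasses.replace(
            panel.base,
            genome_length=int(rng.integers(*panel.genome_length_range)),
            n_ltr=int(rng.integers(*panel.n_ltr_range, endpoint=True)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        genome, truth, _ = simulate_genome(cfg, seq_id=sp, library=library)
        write_fasta([genome], out / "genomes" / f"{sp}.fasta")
        write_truth_gff(truth, sp, out / "truth" / f"{sp}.gff3")
        ploidy_rows.append(
            {"species": sp, "m": int(rng.integers(0, 4)), "n": int(rng.integers(0, 2)),
             "source": "simulated"}
        )
    write_library_fasta(library, out / "library.fasta")
    pd.DataFrame(ploidy_rows).to_csv(out / "ploidy.tsv", sep="\t", index=False)
    logger.info("simulate: %d species under %s", len(species), out)


def annotate_genome(
    genome, library: RepeatLibrary, tandem_kwargs=None, mask_kwargs=None, ltr_kwargs=None
):
    """Annotate one genome: returns (resolved annotations, proportions, elements)."""
    tandem = find_tandem_repeats(genome, **(tandem_kwargs or {}))
    masked = mask_with_library(genome, library, **(mask_kwargs or {}))
    elements = find_ltr_candidates(genome, **(ltr_kwargs or {}))
    combined = tandem + masked + ltr_elements_to_annotations(elements)
    resolved = resolve_overlaps(combined) if combined else []
    props = compute_class_proportions(resolved, genome.length)
    return resolved, props, elements


def _run_annotate(config, out: Path, genomes_dir: Path, library_fasta: Path, species):
    (out / "annotations").mkdir(exist_ok=True)
    (out / "elements").mkdir(exist_ok=True)
    library = RepeatLibrary.from_fasta(library_fasta)
    prop_rows = []
    for sp in species:
        seqs = read_fasta(genomes_dir / f"{sp}.fasta")
        all_resolved, all_elements = [], []
        total_len = sum(s.length for s in seqs)
        class_bases: dict[str, float] = {}
        for genome in seqs:
            resolved, _, elements = annotate_genome(
                genome, library, config.tandem, config.mask, config.ltr
            )
            all_resolved.extend(resolved)
            all_elements.extend(elements)
            for a in resolved:
                class_bases[a.repeat_class] = class_bases.get(a.repeat_class, 0) + a.length
        rows = [
            (a.seq_id, "gsevol", "repeat_region", a.start, a.end, a.score, a.strand,
             {"repeat_class": a.repeat_class, "identity": f"{a.identity:.4f}",
              "family_id": a.family_id})
            for a in all_resolved
        ]
        write_gff3(rows, out / "annotations" / f"{sp}.gff3")
        write_bed(
            [
                (a.seq_id, a.start, a.end, f"{a.repeat_class}:{a.family_id or '.'}",
                 a.score, a.strand)
                for a in all_resolved
            ],
            out / "annotations" / f"{sp}.bed",
        )
        write_elements_tsv(all_elements, out / "elements" / f"{sp}.tsv")
        row = {"species": sp}
        for cls in ("tandem", "LTR", "LINE", "SINE", "DNA", "unknown"):
            row[f"{cls}_pct"] = round(100.0 * class_bases.get(cls, 0) / total_len, 2)
        prop_rows.append(row)
        logger.info(
            "annotate %s: %d annotations, %d LTR candidates",
            sp, len(all_resolved), len(all_elements),
        )
    pd.DataFrame(prop_rows).to_csv(out / "proportions.tsv", sep="\t", index=False)


def _run_date(config, out: Path, genomes_dir: Path, species):
    (out / "dated").mkdir(exist_ok=True)
    summary_rows = []
    for sp in species:
        seqs = {s.seq_id: s for s in read_fasta(genomes_dir / f"{sp}.fasta")}
        elements = read_elements_tsv(out / "elements" / f"{sp}.tsv")
        dated, n_sat = [], 0
        for seq_id, genome in seqs.items():
            mine = [el for el in elements if el.seq_id == seq_id]
            d, sat = date_elements(genome, mine, config.dating)
            dated.extend(d)
            n_sat += sat
        write_elements_tsv(dated, out / "dated" / f"{sp}.tsv")
        mean_myr = species_mean_insertion_time(dated)
        summary_rows.append(
            {"species": sp, "n_elements": len(dated), "n_saturated": n_sat,
             "mean_insertion_myr": mean_myr}
        )
        logger.info(
            "date %s: %d elements, %d saturated, mean %.3f Myr",
            sp, len(dated), n_sat, mean_myr,
        )
    pd.DataFrame(summary_rows).to_csv(out / "dating_summary.tsv", sep="\t", index=False)


def _run_metrics(config, out: Path, genomes_dir: Path, ploidy_tsv: Path, species):
    from .annotate import ClassProportions

    genomes = {sp: read_fasta(genomes_dir / f"{sp}.fasta") for sp in species}
    props_df = pd.read_csv(out / "proportions.tsv", sep="\t").set_index("species")
    proportions = {
        sp: ClassProportions(
            fractions={
                cls: props_df.loc[sp, f"{cls}_pct"] / 100.0
                for cls in ("tandem", "LTR", "LINE", "SINE", "DNA", "unknown")
            },
            total=sum(
                props_df.loc[sp, f"{cls}_pct"] / 100.0
                for cls in ("tandem", "LTR", "LINE", "SINE", "DNA", "unknown")
            ),
        )
        for sp in species
    }
    dating_df = pd.read_csv(out / "dating_summary.tsv", sep="\t").set_index("species")
    mean_myr = dating_df["mean_insertion_myr"].to_dict()
    ploidy = read_ploidy_table(ploidy_tsv)
    table = assemble_species_table(
        genomes, proportions, mean_myr, ploidy, ancestral_mb=config.ancestral_mb
    )
    table.to_tsv(out / "species_factors.tsv")


def _run_correlate(config, out: Path, tree_newick: Path):
    from .metrics import SpeciesTable

    table = SpeciesTable.from_tsv(
        out / "species_factors.tsv", ancestral_mb=config.ancestral_mb
    )
    tree = read_newick(tree_newick)
    results = run_correlation_suite(table, tree)
    results_to_frame(results).to_csv(
        out / "regressions.tsv", sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# evaluation against simulator truth
# ---------------------------------------------------------------------------

def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap as a fraction of the truth interval b."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / (b[1] - b[0]) if b[1] > b[0] else 0.0


def match_ltr_elements(
    predicted: list[LTRElement],
    truth_ltr5: list[tuple[int, int]],
    truth_ltr3: list[tuple[int, int]],
    min_overlap: float = 0.8,
) -> tuple[int, int]:
    """Count truth elements recovered and predictions matching any truth.

    A truth element is recovered when one prediction overlaps both its LTR
    intervals by at least ``min_overlap`` of their lengths.
    """
    recovered = 0
    matched_pred: set[int] = set()
    for t5, t3 in zip(truth_ltr5, truth_ltr3):
        for i, el in enumerate(predicted):
            if (
                _interval_overlap(el.ltr5, t5) >= min_overlap
                and _interval_overlap(el.ltr3, t3) >= min_overlap
            ):
                recovered += 1
                matched_pred.add(i)
                break
    return recovered, len(matched_pred)


def compare_to_truth(outdir: str | Path) -> pd.DataFrame:
    """Per-species evaluation of a synthetic run against its planted truth.

    Reports per-class proportion errors (percentage points), mean insertion
    time error (Myr), and LTR detection sensitivity / precision under the
    80%-overlap-of-both-LTRs rule.
    """
    out = Path(outdir)
    truth_dir = out / "truth"
    if not truth_dir.is_dir():
        raise FileNotFoundError(f"no truth/ directory under {out}; not a synthetic run")
    props = pd.read_csv(out / "proportions.tsv", sep="\t").set_index("species")
    dating = pd.read_csv(out / "dating_summary.tsv", sep="\t").set_index("species")
    genomes_dir = out / "genomes"
    rows = []
    for gff in sorted(truth_dir.glob("*.gff3")):
        sp = gff.stem
        truth = read_gff3(gff)
        glen = sum(s.length for s in read_fasta(genomes_dir / f"{sp}.fasta"))
        row: dict[str, object] = {"species": sp}
        # proportions: truth interval bases per class vs annotated percentages
        for cls in ("tandem", "LTR", "LINE", "DNA"):
            if truth.empty:
                true_pct = 0.0
            else:
                sub = truth[truth["element_class"] == cls]
                true_pct = 100.0 * (sub["end"] - sub["start"]).sum() / glen
            row[f"{cls}_pct_error"] = props.loc[sp, f"{cls}_pct"] - true_pct
        # insertion time
        if not truth.empty and "age_years" in truth.columns:
            ages = truth.loc[
                truth["element_class"] == "LTR", "age_years"
            ].astype(float)
            true_mean = ages.mean() / 1e6 if len(ages) else math.nan
        else:
            true_mean = math.nan
        row["mean_insertion_error_myr"] = (
            dating.loc[sp, "mean_insertion_myr"] - true_mean
        )
        # detection sensitivity / precision
        predicted = read_elements_tsv(out / "dated" / f"{sp}.tsv")
        ltr_truth = truth[truth["element_class"] == "LTR"] if not truth.empty else truth
        if len(ltr_truth):
            lens = ltr_truth["ltr_length"].astype(int)
            t5 = list(zip(ltr_truth["start"], ltr_truth["start"] + lens))
            t3 = list(zip(ltr_truth["end"] - lens, ltr_truth["end"]))
            recovered, matched = match_ltr_elements(predicted, t5, t3)
            row["ltr_sensitivity"] = recovered / len(ltr_truth)
            row["ltr_precision"] = matched / len(predicted) if predicted else math.nan
        else:
            row["ltr_sensitivity"] = math.nan
            row["ltr_precision"] = math.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.4g")
    return df
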