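"""End-to-end orchestration: raw reads -> trimmed tags -> annotation ->
known-miRNA table -> novel-hairpin discovery -> response classes -> targets,
with a deterministic report bundle.

Identical inputs and configuration produce byte-identical reports: every
iteration runs in sorted order, floats are formatted at fixed precision,
and nothing draws randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annot
from . import differential as diff
from . import known as known_mod
from . import novel as novel_mod
from . import preprocess as prep
from . import targets as targets_mod
from .seqio import read_sequences, to_rna, write_gff3

ANNOTATION_CLASS_KEYS = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "exon", "intron")


class PipelineConfigError(ValueError):
    """Configuration problems detected before any computation starts."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    control_reads: str
    treatment_reads: str
    genome: str
    known_mirnas: str | None = None
    annotation_classes: dict[str, str] = field(default_factory=dict)
    transcripts: str | None = None
    cleavage_sites: str | None = None
    outdir: str = "vitismir_out"

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_len: int = 18
    max_len: int = 30
    polya_frac: float = 0.8
    min_seed: int = 8
    trim_max_mismatch: int = 1

    max_mismatch_known: int = 3
    max_shift: int = 4
    fold_threshold: float = 1.5

    hairpin: novel_mod.HairpinCriteria = field(default_factory=novel_mod.HairpinCriteria)
    novel_min_count: int = 5
    star_tolerance: int = 2
    novel_prefix: str = "Vvi-miRC"

    max_mismatch_target: float = 3.0
    positional_target_rules: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hairpin" in raw and isinstance(raw["hairpin"], dict):
            raw["hairpin"] = novel_mod.HairpinCriteria(**raw["hairpin"])
        names = {f.name for f in fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        missing = []
        for label, path in [
            ("control_reads", self.control_reads),
            ("treatment_reads", self.treatment_reads),
            ("genome", self.genome),
            ("known_mirnas", self.known_mirnas),
            ("transcripts", self.transcripts),
            ("cleavage_sites", self.cleavage_sites),
            *[
                (f"annotation_classes[{k}]", v)
                for k, v in sorted(self.annotation_classes.items())
            ],
        ]:
            if path is not None and not Path(path).exists():
                missing.append(f"{label}: {path}")
        if missing:
            raise PipelineConfigError(
                "missing input files: " + "; ".join(missing)
            )
        for key in self.annotation_classes:
            if key not in ANNOTATION_CLASS_KEYS:
                raise PipelineConfigError(f"unknown annotation class {key!r}")
        if not 1 < self.fold_threshold:
            raise PipelineConfigError("fold_threshold must exceed 1")


@dataclass
class PipelineResult:
    """Everything one run computed, ready to be written as the report."""

    config: PipelineConfig
    libraries: dict[str, prep.TagLibrary]
    tallies: dict[str, dict[str, int]]
    categories: dict[str, str]
    breakdowns: dict[str, pd.DataFrame]
    known_table: pd.DataFrame
    candidates: list[novel_mod.HairpinCandidate]
    novel_table: pd.DataFrame
    target_table: pd.DataFrame
    summary: pd.DataFrame

    def write(self, outdir=None) -> dict[str, Path]:
        outdir = Path(outdir if outdir is not None else self.config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for label, df in sorted(self.breakdowns.items()):
            p = outdir / f"category_breakdown_{label}.tsv"
            out = df.copy()
            for col in ("unique_pct", "redundant_pct"):
                out[col] = out[col].map(lambda v: f"{v:.2f}")
            out.to_csv(p, sep="\t")
            paths[f"breakdown_{label}"] = p

        for label, lib in sorted(self.libraries.items()):
            p = outdir / f"size_distribution_{label}.tsv"
            dist_u = prep.size_distribution(lib, "unique")
            dist_r = prep.size_distribution(lib, "redundant")
            with open(p, "w") as fh:
                fh.write("length\tunique_frac\tredundant_frac\n")
                for n in sorted(dist_u):
                    fh.write(f"{n}\t{dist_u[n]:.4f}\t{dist_r[n]:.4f}\n")
            paths[f"sizes_{label}"] = p

        p = outdir / "known_mirnas.tsv"
        diff.write_nc_table(self.known_table, p)
        paths["known"] = p

        p = outdir / "novel_mirnas.tsv"
        diff.write_nc_table(self.novel_table, p)
        paths["novel"] = p

        p = outdir / "novel_hairpins.gff3"
        write_gff3(self.candidates, p)
        paths["gff3"] = p

        p = outdir / "novel_structures.txt"
        with open(p, "w") as fh:
            for c in self.candidates:
                fh.write(f">{c.name} arm={c.arm} five_prime_U={int(c.five_prime_u)}\n")
                fh.write(to_rna(c.precursor) + "\n")
                fh.write(c.structure.dotbracket + "\n")
        paths["structures"] = p

        p = outdir / "targets.tsv"
        self.target_table.to_csv(p, sep="\t", index=False)
        paths["targets"] = p

        p = outdir / "response_summary.tsv"
        self.summary.to_csv(p, sep="\t")
        paths["summary"] = p

        p = outdir / "pipeline_log.txt"
        with open(p, "w") as fh:
            for label in sorted(self.tallies):
                for key, value in self.tallies[label].items():
                    fh.write(f"{label}\t{key}\t{value}\n")
        paths["log"] = p
        return paths


def _load_reads(path) -> list[str]:
    return [rec.residues for rec in read_sequences(path)]


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and return the report bundle in memory."""
    config.validate()
    tallies: dict[str, dict[str, int]] = {}

    with _stage("preprocess"):
        libraries: dict[str, prep.TagLibrary] = {}
        for label, path in (
            ("control", config.control_reads),
            ("treatment", config.treatment_reads),
        ):
            raw = _load_reads(path)
            trimmed = [
                prep.trim_adapter(
                    r, config.adapter, config.min_seed, config.trim_max_mismatch
                )
                for r in raw
            ]
            lib = prep.filter_and_collapse(
                trimmed, label, config.min_len, config.max_len, config.polya_frac
            )
            libraries[label] = lib
            tallies[label] = {
                "raw_reads": len(raw),
                "adapter_only": sum(t is None for t in trimmed),
                "clean_reads": lib.total_redundant,
                "unique_tags": lib.total_unique,
            }

    with _stage("genome"):
        genome = {
            rec.identifier: rec.residues for rec in read_sequences(config.genome)
        }

    all_tags = sorted(set(libraries["control"].tags) | set(libraries["treatment"].tags))

    with _stage("known_mirna"):
        matches: dict[str, known_mod.MatchResult] = {}
        known_table = pd.DataFrame(
            columns=["identifier", "sequence", "nc_control", "nc_treatment"]
        )
        if config.known_mirnas is not None:
            reference = {
                rec.identifier: rec.residues
                for rec in read_sequences(config.known_mirnas)
            }
            matches = known_mod.match_known_bulk(
                all_tags, reference, config.max_mismatch_known, config.max_shift
            )
            agg = known_mod.aggregate_tag_counts(
                matches, libraries["control"].tags, libraries["treatment"].tags
            )
            totals = {l: libraries[l].total_redundant for l in libraries}
            known_table = pd.DataFrame(
                {
                    "identifier": agg.index,
                    "sequence": [to_rna(reference[i]) for i in agg.index],
                    "nc_control": [
                        diff.normalize_counts(c, totals["control"])
                        for c in agg["control"]
                    ],
                    "nc_treatment": [
                        diff.normalize_counts(t, totals["treatment"])
                        for t in agg["treatment"]
                    ],
                }
            )
        known_table = diff.call_responses(known_table, config.fold_threshold)
        tallies["known"] = {
            "tags_matched": len(matches),
            "references_detected": known_table.shape[0],
        }

    with _stage("annotate"):
        class_seqs = {
            label: [rec.residues for rec in read_sequences(path)]
            for label, path in sorted(config.annotation_classes.items())
        }
        index = annot.AnnotationIndex.build(
            class_seqs, genome, config.min_len, config.max_len
        )
        categories = {
            tag: annot.classify_tag(tag, index, known_mirna_hit=tag in matches)
            for tag in all_tags
        }
        breakdowns = {
            label: annot.category_breakdown(
                lib, index, categories={t: categories[t] for t in lib.tags}
            )
            for label, lib in libraries.items()
        }
        tallies["annotate"] = {
            "unannotated_tags": sum(1 for c in categories.values() if c == "unann"),
        }

    with _stage("novel_mirna"):
        unann_counts = {
            tag: {
                label: lib.count(tag) for label, lib in sorted(libraries.items())
            }
            for tag in all_tags
            if categories[tag] == "unann"
        }
        candidates = novel_mod.discover_hairpins(
            unann_counts,
            genome,
            config.hairpin,
            libraries=[libraries["control"], libraries["treatment"]],
            min_count=config.novel_min_count,
            star_tolerance=config.star_tolerance,
            name_prefix=config.novel_prefix,
        )
        totals = {l: libraries[l].total_redundant for l in libraries}
        rows = []
        for c in candidates:
            rows.append(
                {
                    "identifier": c.name,
                    "sequence": to_rna(c.mature),
                    "nc_control": diff.normalize_counts(
                        c.mature_counts.get("control", 0), totals["control"]
                    ),
                    "nc_treatment": diff.normalize_counts(
                        c.mature_counts.get("treatment", 0), totals["treatment"]
                    ),
                    "five_prime_U": int(c.five_prime_u),
                    "star_detected": int(c.star_detected),
                }
            )
            if c.star_detected:
                rows.append(
                    {
                        "identifier": c.name + "*",
                        "sequence": to_rna(c.star),
                        "nc_control": diff.normalize_counts(
                            c.star_counts.get("control", 0), totals["control"]
                        ),
                        "nc_treatment": diff.normalize_counts(
                            c.star_counts.get("treatment", 0), totals["treatment"]
                        ),
                        "five_prime_U": int(to_rna(c.star)[:1] == "U"),
                        "star_detected": 1,
                    }
                )
        novel_table = pd.DataFrame(
            rows,
            columns=[
                "identifier",
                "sequence",
                "nc_control",
                "nc_treatment",
                "five_prime_U",
                "star_detected",
            ],
        )
        novel_table = diff.call_responses(novel_table, config.fold_threshold)
        tallies["novel"] = {
            "candidate_tags": len(unann_counts),
            "hairpins_accepted": len(candidates),
            "stars_detected": sum(c.star_detected for c in candidates),
        }

    with _stage("targets"):
        target_rows = []
        if config.transcripts is not None:
            transcripts = read_sequences(config.transcripts)
            observations: list[targets_mod.CleavageObservation] = []
            if config.cleavage_sites is not None:
                obs_df = pd.read_csv(config.cleavage_sites, sep="\t")
                observations = [
                    targets_mod.CleavageObservation(
                        str(r["transcript_id"]),
                        int(r["coordinate"]),
                        int(r.get("clones", 1)),
                    )
                    for _, r in obs_df.iterrows()
                ]
            rules = (
                targets_mod.PairingRules()
                if config.positional_target_rules
                else None
            )
            for c in candidates:
                for site in targets_mod.predict_targets(
                    c.mature,
                    transcripts,
                    config.max_mismatch_target,
                    rules,
                    mirna_id=c.name,
                ):
                    supported = ""
                    for obs in observations:
                        if obs.transcript_id != site.transcript_id:
                            continue
                        status, pos = targets_mod.validate_cleavage(site, obs)
                        if status == "supported":
                            supported = f"position_{pos}"
                            break
                    target_rows.append(
                        {
                            "mirna_id": site.mirna_id,
                            "transcript_id": site.transcript_id,
                            "start": site.start,
                            "end": site.end,
                            "mismatches": site.mismatches,
                            "cleavage_support": supported,
                        }
                    )
        target_table = pd.DataFrame(
            target_rows,
            columns=[
                "mirna_id",
                "transcript_id",
                "start",
                "end",
                "mismatches",
                "cleavage_support",
            ],
        )
        tallies["targets"] = {"sites": len(target_table)}

    with _stage("summarize"):
        known_sum = known_table[["identifier", "response"]].copy()
        known_sum["origin"] = "known"
        known_sum["star"] = False
        novel_sum = novel_table[["identifier", "response"]].copy()
        novel_sum["origin"] = "novel"
        novel_sum["star"] = novel_sum["identifier"].str.endswith("*")
        summary = diff.summarize_responses(
            pd.concat([known_sum, novel_sum], ignore_index=True)
        )

    return PipelineResult(
        config=config,
        libraries=libraries,
        tallies=tallies,
        categories=categories,
        breakdowns=breakdowns,
        known_table=known_table,
        candidates=candidates,
        novel_table=novel_table,
        target_table=target_table,
        summary=summary,
    )
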