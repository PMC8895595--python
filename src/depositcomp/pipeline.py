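"""End-to-end orchestration: enrich -> rank -> similarity -> CBR scan -> fraction.

One run consumes a measured case/control composition pair plus a candidate
FASTA and produces a machine-readable JSON report: the enriched channel and
per-channel fold changes, the candidate ranking for that channel, profile
similarity of the top candidate against the case measurement, its
low-complexity / residue-bias annotation with coverage, and the fitted
two-component mixture fraction.  Reports carry full provenance (config echo,
package version, input checksums) and contain no timestamps, so identical
inputs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from depositcomp import cbr
from depositcomp.composition import get_scheme, mixture_composition, protein_composition
from depositcomp.enrichment import (
    estimate_mixture_fraction,
    fold_change,
    profile_similarity,
    rank_by_channel,
)
from depositcomp.sequence_io import read_composition_table, read_fasta

logger = logging.getLogger(__name__)

#: Documented exit codes for scripting.
EXIT_OK = 0
EXIT_NO_ENRICHMENT = 3
EXIT_INPUT_ERROR = 4


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run."""

    case_table: str
    control_table: str
    candidates_fasta: str
    output_dir: str
    scheme_name: str = "msa"
    epsilon: float = 1e-4
    weight_mode: str = "molar_chain"
    window: int = 25
    k_trigger: float = 2.2
    k_extend: float = 2.5
    p_threshold: float = 1e-6
    merge_gap: int = 10
    all_targets: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def scan_params(self) -> cbr.ScanParams:
        return cbr.ScanParams(
            window=self.window,
            k_trigger=self.k_trigger,
            k_extend=self.k_extend,
            p_threshold=self.p_threshold,
            merge_gap=self.merge_gap,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _segments_json(segments: list[cbr.BiasSegment]) -> list[dict]:
    return [
        {
            "start": s.start,
            "end": s.end,
            "kind": s.kind,
            "dominant_residues": "".join(sorted(s.dominant_residues)),
            "score": round(s.score, 6),
        }
        for s in segments
    ]


def _analyse_target(channel, candidates, case_measured, scheme, config):
    """Ranking, similarity, CBR annotation and fraction fit for one channel."""
    ranking = rank_by_channel(candidates, channel, scheme)
    by_id = {r.id: r for r in candidates}
    top = by_id[ranking.top_id()]
    top_comp = protein_composition(top, scheme)
    similarity = profile_similarity(top_comp, case_measured)

    params = config.scan_params()
    channel_residues = set(scheme.residues_for_channel(channel))
    bias_segments = cbr.scan_residue_bias(top, channel_residues, params)
    lc_segments = cbr.scan_low_complexity(top, params)
    bias_coverage = cbr.coverage(bias_segments, len(top))

    others = [r for r in candidates if r.id != top.id]
    if others:
        background = mixture_composition(
            [(r, 1.0) for r in others], scheme, weight_mode=config.weight_mode
        )
        est = estimate_mixture_fraction(case_measured, top_comp, background)
        fraction = {
            "estimate": est.fraction,
            "residual": est.residual,
            "degenerate": est.degenerate,
        }
    else:
        fraction = None
        logger.warning("single-candidate input: mixture fraction not estimated")

    return {
        "channel": channel,
        "ranking": [
            {"id": pid, "fraction": frac, "rank": rank}
            for pid, frac, rank in ranking.rows
        ],
        "excluded_candidates": list(ranking.excluded),
        "top_candidate": top.id,
        "similarity": {"pearson": similarity.pearson, "jsd": similarity.jsd},
        "bias_segments": _segments_json(bias_segments),
        "low_complexity_segments": _segments_json(lc_segments),
        "bias_coverage": bias_coverage,
        "mixture_fraction": fraction,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write ``report.json`` (plus per-target TSVs).

    Returns the report dict.  If no channel is called enriched the report is
    still written, with status ``no-enrichment`` and the ranking stages
    skipped.
    """
    for path in (config.case_table, config.control_table, config.candidates_fasta):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    scheme = get_scheme(config.scheme_name)
    case = read_composition_table(config.case_table, scheme)
    control = read_composition_table(config.control_table, scheme)
    candidates = read_fasta(config.candidates_fasta)
    logger.info(
        "loaded %d candidates; case sha=%s control sha=%s",
        len(candidates), _sha256(config.case_table)[:12],
        _sha256(config.control_table)[:12],
    )

    enrichment = fold_change(case, control, epsilon=config.epsilon)
    report: dict = {
        "status": "ok",
        "scheme": config.scheme_name,
        "enrichment": {
            "fold_change": {ch: v for ch, v in enrichment.fold_change.items()},
            "target_channels": list(enrichment.target_channels),
            "epsilon": enrichment.epsilon,
            "epsilon_channels": list(enrichment.epsilon_channels),
        },
        "targets": [],
        "provenance": {
            # output_dir is where the report lands, not an analytical input;
            # leaving it out keeps reports byte-identical across locations
            "config": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "output_dir"
            },
            "version": _package_version(),
            "inputs": {
                "case_table": _sha256(config.case_table),
                "control_table": _sha256(config.control_table),
                "candidates_fasta": _sha256(config.candidates_fasta),
            },
        },
    }

    if not enrichment.target_channels:
        report["status"] = "no-enrichment"
        logger.warning("no enriched channel called; ranking skipped")
    else:
        channels = (
            enrichment.target_channels
            if config.all_targets
            else enrichment.target_channels[:1]
        )
        for ch in channels:
            report["targets"].append(
                _analyse_target(ch, candidates, case, scheme, config)
            )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_tables(report, outdir)
    return report


def _write_tables(report: dict, outdir: Path) -> None:
    """Human-readable TSV companions to the JSON report (1-based coordinates)."""
    for target in report["targets"]:
        ch = target["channel"]
        with open(outdir / f"ranking_{ch}.tsv", "w") as fh:
            fh.write("rank\tid\tfraction\n")
            for row in target["ranking"]:
                fh.write(f"{row['rank']}\t{row['id']}\t{row['fraction']:.6f}\n")
        with open(outdir / f"segments_{target['top_candidate']}.tsv", "w") as fh:
            fh.write("id\tstart\tend\tkind\tdominant_residues\tscore\n")
            for seg in target["bias_segments"] + target["low_complexity_segments"]:
                fh.write(
                    f"{target['top_candidate']}\t{seg['start'] + 1}\t{seg['end']}\t"
                    f"{seg['kind']}\t{seg['dominant_residues']}\t{seg['score']:.4f}\n"
                )


def _package_version() -> str:
    from depositcomp import __version__

    return __version__
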