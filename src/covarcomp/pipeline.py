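"""End-to-end comparison of covariation between two alignments.

Runs preprocessing, the Zpx statistic, pair-set comparison, propensity
correlation, mechanism classification and (optionally) structural context,
and assembles everything into one JSON-serializable report.  All column
indices in the report are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import comparison as cmp
from . import mechanisms as mech
from .alignment import (
    Alignment,
    filter_gapped_sequences,
    redundancy_filter,
)
from .covariation import (
    CovariationResult,
    CovaryingPairSet,
    DegenerateInputError,
    compute_covariation,
    top_covarying_pairs,
)
from .propensity import pair_propensity, propensity_correlation
from .structure import (
    StructureModel,
    build_context,
    burial_class,
    cb_neighbor_counts,
    min_heavy_atom_distance,
    pair_burial_class,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for every pipeline stage, with the standard defaults."""

    k_sd: float = 2.0                 # Zpx threshold: mean + k·SD
    near_far_cutoff: int = 10         # residues, inclusive "near"
    top_n_transitions: int = 10
    identity_threshold: float = 0.8   # redundancy filter
    occupancy: float = 0.9            # gap filter
    apply_filters: bool = True
    annotations: mech.ResidueAnnotations = field(
        default_factory=mech.ResidueAnnotations
    )


def _pairs_1based(pairs) -> list[list[int]]:
    return sorted([i + 1, j + 1] for (i, j) in pairs)


def _alignment_summary(label: str, aln: Alignment, result: CovariationResult,
                       pairs: CovaryingPairSet) -> dict[str, Any]:
    return {
        "label": label,
        "n_seq": aln.n_seq,
        "n_col": aln.n_col,
        "n_ungapped_columns": len(result.columns),
        "mean_zpx": result.mean_zpx,
        "sd_zpx": result.sd_zpx,
        "zpx_threshold": pairs.threshold,
        "n_covarying_pairs": len(pairs),
        "covarying_pairs": _pairs_1based(pairs),
    }


def preprocess(aln: Alignment, config: PipelineConfig) -> Alignment:
    """Gap-pattern filter (against the alignment's own consensus) followed
    by greedy redundancy removal."""
    filtered = filter_gapped_sequences(aln, aln, occupancy=config.occupancy)
    return redundancy_filter(filtered, identity_threshold=config.identity_threshold)


def run_comparison(
    natural: Alignment,
    designed: Alignment,
    structure: StructureModel | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, Any]:
    """Full natural-vs-designed covariation comparison.

    Returns a plain dict (the ComparisonReport) ready for JSON emission.
    Structural sections are included only when ``structure`` is given.
    """
    config = config or PipelineConfig()
    if natural.n_col != designed.n_col:
        raise ValueError(
            f"column-frame mismatch: {natural.n_col} vs {designed.n_col}"
        )
    if config.apply_filters:
        natural = preprocess(natural, config)
        designed = preprocess(designed, config)

    res_nat = compute_covariation(natural)
    res_des = compute_covariation(designed)
    pairs_nat = top_covarying_pairs(res_nat, k=config.k_sd)
    pairs_des = top_covarying_pairs(res_des, k=config.k_sd)

    overlap_report = cmp.compare_pair_sets(pairs_nat, pairs_des)
    classification = cmp.classify_pairs(pairs_nat, pairs_des)

    near_nat, far_nat = cmp.split_near_far(pairs_nat, config.near_far_cutoff)
    near_des, far_des = cmp.split_near_far(pairs_des, config.near_far_cutoff)

    report: dict[str, Any] = {
        "natural": _alignment_summary("natural", natural, res_nat, pairs_nat),
        "designed": _alignment_summary("designed", designed, res_des, pairs_des),
        "overlap": asdict(overlap_report),
        "classification": {
            "overlap": _pairs_1based(classification.overlap),
            "natural_specific": _pairs_1based(classification.a_specific),
            "designed_specific": _pairs_1based(classification.b_specific),
        },
        "near_far": {
            "cutoff": config.near_far_cutoff,
            "near_percent_overlap": cmp.overlap_similarity(near_nat, near_des),
            "far_percent_overlap": cmp.overlap_similarity(far_nat, far_des),
            "n_near": {"natural": len(near_nat), "designed": len(near_des)},
            "n_far": {"natural": len(far_nat), "designed": len(far_des)},
        },
    }

    # pair propensities at pairs covarying in both alignments
    overlap_pairs = set(classification.overlap)
    propensity_section: dict[str, Any] = {"n_overlap_pairs": len(overlap_pairs)}
    if overlap_pairs:
        try:
            tab_nat = pair_propensity(natural, overlap_pairs)
            tab_des = pair_propensity(designed, overlap_pairs)
            propensity_section["correlation_r"] = propensity_correlation(
                tab_nat, tab_des
            )
        except DegenerateInputError as exc:
            propensity_section["correlation_r"] = None
            propensity_section["note"] = str(exc)
    else:
        propensity_section["correlation_r"] = None
    report["propensity"] = propensity_section

    # covariation mechanisms
    trans_nat = mech.top_transitions(
        natural, pairs_nat, n=config.top_n_transitions, annotations=config.annotations
    )
    trans_des = mech.top_transitions(
        designed, pairs_des, n=config.top_n_transitions, annotations=config.annotations
    )
    all_nat = [r for recs in trans_nat.values() for r in recs]
    all_des = [r for recs in trans_des.values() for r in recs]
    report["mechanisms"] = {
        "natural_distribution": (
            mech.mechanism_distribution(all_nat) if all_nat else None
        ),
        "designed_distribution": (
            mech.mechanism_distribution(all_des) if all_des else None
        ),
        "per_class_percent_overlap": mech.mechanism_overlap(trans_nat, trans_des),
        "natural_pair_mechanisms": {
            f"{i + 1},{j + 1}": mech.pair_mechanism(r)
            for (i, j), r in sorted(trans_nat.items())
        },
        "designed_pair_mechanisms": {
            f"{i + 1},{j + 1}": mech.pair_mechanism(r)
            for (i, j), r in sorted(trans_des.items())
        },
    }
    report["_transitions"] = {"natural": trans_nat, "designed": trans_des}

    if structure is not None:
        report["structure"] = structure_section(
            structure, classification, pairs_nat, pairs_des
        )
    return report


def structure_section(
    structure: StructureModel,
    classification: cmp.PairClassification,
    pairs_nat: CovaryingPairSet,
    pairs_des: CovaryingPairSet,
) -> dict[str, Any]:
    """Pair-distance and burial summaries for the three classification sets."""
    col_to_res = {c: r for r, c in structure.column_map.items()}
    counts = cb_neighbor_counts(structure)
    burial = [burial_class(int(c)) for c in counts]

    def distances(pairs) -> list[float]:
        out = []
        for (i, j) in sorted(pairs):
            if i in col_to_res and j in col_to_res:
                out.append(
                    min_heavy_atom_distance(structure, col_to_res[i], col_to_res[j])
                )
        return out

    def burial_pairs(pairs) -> dict[str, int]:
        tally = {"exposed": 0, "intermediate": 0, "buried": 0}
        for (i, j) in pairs:
            if i in col_to_res and j in col_to_res:
                cls = pair_burial_class(
                    burial[col_to_res[i]], burial[col_to_res[j]]
                )
                tally[cls] += 1
        return tally

    sets = {
        "overlap": set(classification.overlap),
        "natural_specific": set(classification.a_specific),
        "designed_specific": set(classification.b_specific),
    }
    section: dict[str, Any] = {
        "cb_counts": [int(c) for c in counts],
        "burial": burial,
        "pair_distances": {
            name: {
                "distances": distances(s),
                "median": (float(np.median(distances(s))) if distances(s) else None),
            }
            for name, s in sets.items()
        },
        "pair_burial": {name: burial_pairs(s) for name, s in sets.items()},
    }
    return section


def report_to_json(report: dict[str, Any]) -> str:
    """Deterministic JSON serialization (sorted keys, no raw records)."""
    public = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(public, indent=2, sort_keys=True)


def write_report(report: dict[str, Any], out_dir: str | Path) -> None:
    """Write report.json plus TSV side files to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report) + "\n")

    with open(out / "pairs.tsv", "w") as fh:
        fh.write("set\tcolumn_i\tcolumn_j\n")
        for name in ("overlap", "natural_specific", "designed_specific"):
            for (i, j) in report["classification"][name]:
                fh.write(f"{name}\t{i}\t{j}\n")

    trans = report.get("_transitions", {})
    with open(out / "transitions.tsv", "w") as fh:
        fh.write(
            "source\tcolumn_i\tcolumn_j\tfrom_pair\tto_pair\tscore\tmechanism\n"
        )
        for source, records in sorted(trans.items()):
            for (i, j), recs in sorted(records.items()):
                for r in recs:
                    fh.write(
                        f"{source}\t{i + 1}\t{j + 1}\t"
                        f"{''.join(r.from_pair)}\t{''.join(r.to_pair)}\t"
                        f"{r.score:.6f}\t{r.mechanism}\n"
                    )
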