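"""End-to-end orchestration: standardize -> fragment -> rule-of-three ->
descriptors -> synthetic accessibility -> diversity -> overlap -> scaffolds
-> embeddings, from a single configuration, producing a CSV report bundle
and a run manifest.

Defaults equal the study parameters (MW cutoff 1000 Da, inclusive
rule-of-three thresholds, ten subsets of 5000, k=50/kc=10 tree embedding,
perplexity-40/300-iteration t-SNE); overrides are recorded in the manifest.
A single master seed fans out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import __version__
from .chem_io import LibraryRegistry, read_library, write_library
from .chemspace import knn_graph, tmap_layout, tsne_embed
from .overlap_freq import frequency_table, overlap, scaffold_summary
from .properties import RO3_DEFAULTS, filter_ro3, library_descriptor_summary
from .recap import fragment_library
from .sa_score import EASY_SYNTHESIS_THRESHOLD, library_sa_summary
from .similarity import FingerprintSpec, SubsampleScheme, diversity_distribution, fingerprint_matrix
from .standardize import standardize_library

logger = logging.getLogger(__name__)

_SEED_OFFSETS = {"subsample": 101, "embedding": 202, "tsne": 303}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, library: str | None, cause: Exception):
        super().__init__(f"stage {stage!r} failed for library {library!r}: {cause}")
        self.stage = stage
        self.library = library
        self.cause = cause


@dataclass
class PipelineConfig:
    registry: LibraryRegistry
    out_dir: str
    mw_cutoff: float = 1000.0
    ro3_thresholds: dict = field(default_factory=lambda: dict(RO3_DEFAULTS))
    sa_threshold: float = EASY_SYNTHESIS_THRESHOLD
    subsample: SubsampleScheme = field(default_factory=SubsampleScheme)
    fingerprints: tuple = ("maccs166", "morgan2_1024")
    embed_methods: tuple = ("tmap",)
    embed_fingerprint: str = "maccs166"
    embed_k: int = 50
    embed_kc: int = 10
    tsne_perplexity: float = 40.0
    tsne_iterations: int = 300
    mw_window: tuple = (70.0, 300.0)
    top_k: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle)
        registry = LibraryRegistry.load(raw.pop("registry"))
        out_dir = raw.pop("out_dir")
        scheme = raw.pop("subsample", None)
        config = cls(registry=registry, out_dir=out_dir)
        if scheme:
            config.subsample = SubsampleScheme(**scheme)
        for key, value in raw.items():
            if not hasattr(config, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(config, key, tuple(value) if isinstance(value, list) else value)
        return config


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every registered library; returns the manifest.

    Any stage failure aborts with the stage name and offending library and
    leaves a ``FAILED`` marker file in the output directory.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    failed_marker = os.path.join(config.out_dir, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            name: config.seed + offset for name, offset in _SEED_OFFSETS.items()
        },
        "parameters": {
            "mw_cutoff": config.mw_cutoff,
            "ro3_thresholds": config.ro3_thresholds,
            "sa_threshold": config.sa_threshold,
            "subsample": dataclasses.asdict(config.subsample),
            "fingerprints": list(config.fingerprints),
            "mw_window": list(config.mw_window),
        },
        "libraries": {},
    }
    stage = "setup"
    library = None
    try:
        standardized = {}
        fragments = {}
        ro3_sets = {}
        attrition_rows = []
        for entry in config.registry:
            library = entry.name
            stage = "read"
            records = read_library(entry)
            stage = "standardize"
            std_records, report = standardize_library(records)
            standardized[entry.name] = std_records
            stage = "fragment"
            frags, frag_stats = fragment_library(std_records, config.mw_cutoff)
            fragments[entry.name] = frags
            stage = "ro3"
            ro3_frags, ro3_rate = filter_ro3(frags, config.ro3_thresholds)
            ro3_sets[entry.name] = ro3_frags
            frag_path = os.path.join(config.out_dir, f"fragments_{entry.name}.smi")
            _write_fragments(frags, frag_path)
            _write_fragments(
                ro3_frags, os.path.join(config.out_dir, f"fragments_ro3_{entry.name}.smi")
            )
            attrition_rows.append(
                {
                    "library": entry.name,
                    "n_input": report.n_input,
                    "n_standardized": report.n_after_dedup,
                    "n_skipped_mw": frag_stats.n_skipped_mw,
                    "n_fragments": len(frags),
                    "n_fragments_ro3": len(ro3_frags),
                    "pct_fragments_ro3": _pct(len(ro3_frags), len(frags)),
                }
            )
            manifest["libraries"][entry.name] = {
                "n_input": report.n_input,
                "n_standardized": report.n_after_dedup,
                "n_fragments": len(frags),
                "n_fragments_ro3": len(ro3_frags),
            }
        stage = "attrition_table"
        library = None
        pd.DataFrame(attrition_rows).to_csv(
            os.path.join(config.out_dir, "attrition.csv"), index=False
        )

        stage = "overlap"
        names = list(fragments)
        overlap_rows = []
        for i, name_a in enumerate(names):
            for name_b in names[i + 1 :]:
                for tag, sets in (("fragments", fragments), ("ro3", ro3_sets)):
                    result = overlap(sets[name_a], sets[name_b], name_a, name_b)
                    overlap_rows.append(
                        {
                            "subset": tag,
                            "library_a": name_a,
                            "library_b": name_b,
                            "n_a": result.n_a,
                            "n_b": result.n_b,
                            "n_shared": result.n_shared,
                            "pct_shared_a": round(result.pct_shared_a, 1),
                            "pct_shared_b": round(result.pct_shared_b, 1),
                        }
                    )
        pd.DataFrame(overlap_rows).to_csv(
            os.path.join(config.out_dir, "overlap.csv"), index=False
        )

        stage = "frequency"
        for name, frags in fragments.items():
            table = frequency_table(
                frags, top_k=config.top_k, mw_window=config.mw_window
            )
            pd.DataFrame(
                table.entries, columns=["smiles", "percentage", "occurrence"]
            ).to_csv(
                os.path.join(config.out_dir, f"top_fragments_{name}.csv"), index=False
            )

        stage = "descriptors"
        summary_columns = {}
        for name, frags in fragments.items():
            library = name
            mols = _mols_of(frags)
            if mols:
                summary_columns[name] = library_descriptor_summary(mols)
        library = None
        if summary_columns:
            pd.DataFrame(summary_columns).to_csv(
                os.path.join(config.out_dir, "descriptor_means.csv")
            )

        stage = "sa_score"
        sa_rows = []
        for name, frags in fragments.items():
            library = name
            mols = _mols_of(frags)
            if not mols:
                continue
            summary = library_sa_summary(mols, config.sa_threshold)
            sa_rows.append(
                {
                    "library": name,
                    "mean_sa": round(summary.mean, 2),
                    "n_above_threshold": summary.n_above_threshold,
                    "fraction_above_threshold": round(
                        summary.fraction_above_threshold, 4
                    ),
                }
            )
        library = None
        pd.DataFrame(sa_rows).to_csv(
            os.path.join(config.out_dir, "sa_summary.csv"), index=False
        )

        stage = "diversity"
        scheme = dataclasses.replace(
            config.subsample, seed=config.seed + _SEED_OFFSETS["subsample"]
        )
        for name, frags in fragments.items():
            library = name
            mols = _mols_of(frags)
            if len(mols) < 2:
                continue
            for kind in config.fingerprints:
                dist = diversity_distribution(mols, FingerprintSpec(kind), scheme)
                pd.DataFrame(
                    {
                        "similarity": dist.cdf_similarity,
                        "cumulative_fraction": dist.cdf_fraction,
                    }
                ).to_csv(
                    os.path.join(config.out_dir, f"diversity_cdf_{name}_{kind}.csv"),
                    index=False,
                )
                manifest["libraries"][name][f"median_tanimoto_{kind}"] = dist.median
        library = None

        stage = "scaffolds"
        scaffold_rows = []
        for name, frags in fragments.items():
            summary = scaffold_summary(_mols_of(frags))
            scaffold_rows.append(
                {
                    "library": name,
                    "n_distinct": summary.n_distinct,
                    "n_nonheterocyclic": summary.n_nonheterocyclic,
                    "n_nitrogen_containing": summary.n_nitrogen_containing,
                    "n_fused": summary.n_fused,
                    "n_ortho_fused": summary.n_ortho_fused,
                }
            )
        pd.DataFrame(scaffold_rows).to_csv(
            os.path.join(config.out_dir, "scaffolds.csv"), index=False
        )

        stage = "embedding"
        labeled = [
            (name, fragment.canonical_smiles)
            for name, frags in ro3_sets.items()
            for fragment in frags
        ]
        if len(labeled) >= 5:
            labels = [name for name, _ in labeled]
            mols = [Chem.MolFromSmiles(s) for _, s in labeled]
            fps = fingerprint_matrix(mols, FingerprintSpec(config.embed_fingerprint))
            for method in config.embed_methods:
                if method == "tmap":
                    graph = knn_graph(
                        fps,
                        k=config.embed_k,
                        kc=config.embed_kc,
                        seed=config.seed + _SEED_OFFSETS["embedding"],
                    )
                    result = tmap_layout(graph, labels=labels)
                else:
                    result = tsne_embed(
                        fps,
                        perplexity=config.tsne_perplexity,
                        n_iter=config.tsne_iterations,
                        seed=config.seed + _SEED_OFFSETS["tsne"],
                        labels=labels,
                    )
                frame = pd.DataFrame(
                    {
                        "id": range(len(labeled)),
                        "library": labels,
                        "smiles": [s for _, s in labeled],
                        "x": result.coords[:, 0],
                        "y": result.coords[:, 1],
                    }
                )
                frame.to_csv(
                    os.path.join(config.out_dir, f"embedding_{method}.csv"), index=False
                )
                if result.edges:
                    pd.DataFrame(
                        result.edges, columns=["source", "target", "weight"]
                    ).to_csv(
                        os.path.join(config.out_dir, f"embedding_{method}_edges.csv"),
                        index=False,
                    )

        stage = "manifest"
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:  # noqa: BLE001 - deliberate catch-all for marker
        with open(failed_marker, "w") as handle:
            handle.write(f"stage={stage} library={library} error={exc}\n")
        raise PipelineError(stage, library, exc) from exc


def _mols_of(fragments) -> list[Chem.Mol]:
    mols = [Chem.MolFromSmiles(f.canonical_smiles) for f in fragments]
    return [m for m in mols if m is not None]


def _write_fragments(fragments, path: str) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["smiles", "occurrence", "n_parents", "rules"])
        for fragment in sorted(fragments, key=lambda f: (-f.occurrence, f.canonical_smiles)):
            writer.writerow(
                [
                    fragment.canonical_smiles,
                    fragment.occurrence,
                    len(fragment.parents),
                    "|".join(sorted(fragment.rules_applied)),
                ]
            )
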