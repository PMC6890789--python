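"""Atlas-connectivity interrogation around a lesion.

Viral-tracing atlases record, per injection experiment, the projection
volume reaching each target structure; connection strength is the
normalized projection volume (projection volume divided by tracer volume
in the injection structure).  Not every region has its own experiment, so
queries walk the ontology upward until an experiment-bearing ancestor is
found.  Target lists are filtered to mid-ontology structures (graph depth
>= 5 and graph order >= 6), stripped of the injection site's own
descendants, ranked by strength, and can be assembled into matrices,
common-target tallies, or degeneration reports joining in cell densities.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import OntologyTree

__all__ = [
    "ConnectivityTable",
    "load_connectivity_table",
    "find_injection_experiment",
    "ranked_targets",
    "projection_matrix",
    "common_targets",
    "degeneration_report",
    "export_graph",
]

REQUIRED_COLUMNS = (
    "experiment_id",
    "injection_structure_id",
    "target_structure_id",
    "normalized_projection_volume",
)


@dataclasses.dataclass
class ConnectivityTable:
    """Experiment→target projection records plus provenance."""

    records: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"connectivity table missing columns: {missing}")
        dup = self.records.duplicated(subset=["experiment_id", "target_structure_id"])
        if dup.any():
            raise ValueError("duplicate (experiment, target) pairs in table")
        # consistency check when both raw and normalized volumes are present
        if {"projection_volume", "injection_volume_mm3"} <= set(self.records.columns):
            expected = self.records["projection_volume"] / self.records["injection_volume_mm3"]
            bad = ~np.isclose(
                expected, self.records["normalized_projection_volume"], rtol=1e-4, atol=1e-12
            )
            if bad.any():
                raise ValueError(
                    f"{int(bad.sum())} records violate normalized = projection / injection volume"
                )

    def experiments_for(self, structure_id: int) -> pd.DataFrame:
        return self.records[self.records["injection_structure_id"] == structure_id]

    def targets_of(self, experiment_id: int) -> pd.DataFrame:
        return self.records[self.records["experiment_id"] == experiment_id]


def load_connectivity_table(
    path: str | Path, strain: str | None = "C57BL/6J"
) -> ConnectivityTable:
    """Load a CSV projection table, restricted to one strain by default.

    The wild-type strain restriction matches standard practice for
    building a homogeneous reference connectome; pass ``strain=None`` to
    keep every record.
    """
    df = pd.read_csv(path)
    if strain is not None and "strain" in df.columns:
        df = df[df["strain"] == strain].reset_index(drop=True)
    return ConnectivityTable(df, source=str(path))


def find_injection_experiment(
    label_id: int, table: ConnectivityTable, ontology: OntologyTree
) -> tuple[int, int] | None:
    """Experiment for a label, walking ancestors nearest-first on a miss.

    Returns ``(experiment_id, matched_structure_id)`` or None when no
    structure up to the root carries an experiment.  When several
    experiments exist at the matched structure the lowest experiment id
    wins (deterministic).
    """
    if label_id not in ontology:
        raise KeyError(f"unknown ontology id {label_id}")
    for sid in [label_id] + [n.id for n in ontology.ancestors(label_id)]:
        hits = table.experiments_for(sid)
        if len(hits):
            return int(hits["experiment_id"].min()), sid
    return None


def ranked_targets(
    experiment_id: int,
    table: ConnectivityTable,
    ontology: OntologyTree,
    injection_structure: int,
    min_depth: int = 5,
    min_order: int = 6,
    exclude_region_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Targets of an experiment, filtered and ranked by strength.

    Removes major structures (graph depth < ``min_depth`` or graph order
    < ``min_order``), descendants of the injection structure (trivial
    spill-over), and any explicitly excluded regions (e.g. regions
    overlapping a lesion mask).  Sorted by normalized projection volume
    descending, ties by ascending target id.
    """
    hits = table.targets_of(experiment_id)
    if len(hits) == 0:
        raise KeyError(f"unknown experiment {experiment_id}")
    children = ontology.descendants(injection_structure) | {injection_structure}
    rows = []
    for _, rec in hits.iterrows():
        tid = int(rec["target_structure_id"])
        if tid not in ontology:
            warnings.warn(f"target {tid} absent from ontology; dropped", stacklevel=2)
            continue
        node = ontology[tid]
        if node.graph_depth < min_depth or node.graph_order < min_order:
            continue
        if tid in children:
            continue
        if exclude_region_ids and tid in exclude_region_ids:
            continue
        rows.append(
            {
                "target_structure_id": tid,
                "acronym": node.acronym,
                "normalized_projection_volume": float(rec["normalized_projection_volume"]),
                "hemisphere": rec.get("hemisphere", "ipsi"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "target_structure_id",
            "acronym",
            "normalized_projection_volume",
            "hemisphere",
        ],
    )
    df = df.sort_values(
        ["normalized_projection_volume", "target_structure_id"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def projection_matrix(
    injection_label_ids: list[int],
    table: ConnectivityTable,
    ontology: OntologyTree,
    top_k: int = 5,
    **filter_kwargs,
) -> pd.DataFrame:
    """Injection × ranked-target matrix of normalized projection volumes.

    Row i holds the top-k targets of injection i; unresolvable injections
    (no experiment up to the root) yield an all-NaN row.  Columns are
    target rank positions; a companion ``target_<rank>`` column records
    which structure occupies each cell.
    """
    rows = {}
    target_ids = {}
    for lid in injection_label_ids:
        found = find_injection_experiment(lid, table, ontology)
        acr = ontology[lid].acronym
        if found is None:
            rows[acr] = [np.nan] * top_k
            target_ids[acr] = [None] * top_k
            continue
        exp_id, matched = found
        ranked = ranked_targets(exp_id, table, ontology, matched, **filter_kwargs)
        weights = ranked["normalized_projection_volume"].tolist()[:top_k]
        tids = ranked["target_structure_id"].tolist()[:top_k]
        weights += [np.nan] * (top_k - len(weights))
        tids += [None] * (top_k - len(tids))
        rows[acr] = weights
        target_ids[acr] = tids
    mat = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rank_{i + 1}" for i in range(top_k)]
    )
    for i in range(top_k):
        mat[f"target_{i + 1}"] = [target_ids[acr][i] for acr in mat.index]
    return mat


def common_targets(
    injection_label_ids: list[int],
    table: ConnectivityTable,
    ontology: OntologyTree,
    n: int = 50,
    **filter_kwargs,
) -> pd.DataFrame:
    """Targets ranked by how many injection sites project to them.

    Ties are broken by mean normalized projection volume (descending),
    then ascending target id.
    """
    tallies: dict[int, list[float]] = {}
    resolved = 0
    for lid in injection_label_ids:
        found = find_injection_experiment(lid, table, ontology)
        if found is None:
            continue
        resolved += 1
        exp_id, matched = found
        ranked = ranked_targets(exp_id, table, ontology, matched, **filter_kwargs)
        for _, rec in ranked.iterrows():
            tallies.setdefault(int(rec["target_structure_id"]), []).append(
                float(rec["normalized_projection_volume"])
            )
    if resolved == 0:
        raise ValueError("no injection label could be resolved to an experiment")
    rows = [
        {
            "target_structure_id": tid,
            "acronym": ontology[tid].acronym,
            "n_injections": len(ws),
            "mean_normalized_projection_volume": float(np.mean(ws)),
        }
        for tid, ws in tallies.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["n_injections", "mean_normalized_projection_volume", "target_structure_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return df.head(n).reset_index(drop=True)


def degeneration_report(
    injection_label_ids: list[int],
    table: ConnectivityTable,
    ontology: OntologyTree,
    density_table: pd.DataFrame,
    **filter_kwargs,
) -> pd.DataFrame:
    """Per-injection targets annotated with normalized density and 2-SD flag.

    ``density_table`` is the output of
    :func:`clarimap.features.normalize_and_flag` (region_id,
    normalized_density, flagged).  Targets missing from it are listed with
    NaN density and flagged = None (absent marker).
    """
    dens = density_table.set_index("region_id")
    rows = []
    for lid in injection_label_ids:
        found = find_injection_experiment(lid, table, ontology)
        if found is None:
            continue
        exp_id, matched = found
        ranked = ranked_targets(exp_id, table, ontology, matched, **filter_kwargs)
        ipsi = ranked[ranked["hemisphere"].fillna("ipsi") == "ipsi"]
        for _, rec in ipsi.iterrows():
            tid = int(rec["target_structure_id"])
            if tid in dens.index:
                nd = float(dens.loc[tid, "normalized_density"])
                flag = bool(dens.loc[tid, "flagged"])
            else:
                nd, flag = np.nan, None
            rows.append(
                {
                    "injection_id": lid,
                    "injection_acronym": ontology[lid].acronym,
                    "target_structure_id": tid,
                    "target_acronym": rec["acronym"],
                    "normalized_projection_volume": rec["normalized_projection_volume"],
                    "normalized_density": nd,
                    "flagged": flag,
                }
            )
    return pd.DataFrame(rows)


def export_graph(
    weights: pd.DataFrame,
    ontology: OntologyTree,
    threshold: float = 0.0,
    source_col: str = "injection_id",
    target_col: str = "target_structure_id",
    weight_col: str = "normalized_projection_volume",
    groups: dict[int, str] | None = None,
) -> dict:
    """Node/link JSON document for network-graph display.

    Nodes carry region id, acronym, and an optional group tag (e.g.
    in-lesion vs outside); links below ``threshold`` are dropped.
    """
    links = []
    node_ids: set[int] = set()
    for _, rec in weights.iterrows():
        w = float(rec[weight_col])
        if not np.isfinite(w) or w < threshold:
            continue
        src, dst = int(rec[source_col]), int(rec[target_col])
        links.append({"source": src, "target": dst, "weight": w})
        node_ids.update((src, dst))
    nodes = [
        {
            "id": nid,
            "acronym": ontology[nid].acronym if nid in ontology else str(nid),
            "group": (groups or {}).get(nid, "other"),
        }
        for nid in sorted(node_ids)
    ]
    return {"nodes": nodes, "links": links}


def save_graph(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1))
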