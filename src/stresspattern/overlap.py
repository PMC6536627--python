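"""Cross-strain overlap partition, direction concordance, and clustering.

Passing calls from the three strains are partitioned into the seven
exclusive Venn regions (three strain-unique, three pairwise exclusive of
the triple, and the triple).  Concordance asks, for the transcripts shared
by a strain pair or triple, how many respond in the same direction in all
of them.  Shared transcripts are hierarchically clustered on their
per-strain stress contrast (mean CMS-R minus mean NH-R, log2 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class OverlapPartition:
    """Exclusive Venn partition of passing calls.

    ``regions`` maps a region key — strain labels joined by ``&`` in the
    order given by ``strains`` (e.g. ``"B"``, ``"B&N"``, ``"B&N&D"``) —
    to a sorted list of transcript ids.  Pairwise regions exclude the
    triple.  ``directions`` maps transcript -> {strain: "UP"/"DOWN"} for
    every strain in which the transcript passes.
    """

    strains: tuple[str, ...]
    regions: dict[str, list[str]]
    directions: dict[str, dict[str, str]]

    def region_key(self, members: set[str]) -> str:
        return "&".join(s for s in self.strains if s in members)

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    @property
    def multi_strain_transcripts(self) -> list[str]:
        out: list[str] = []
        for key, members in self.regions.items():
            if "&" in key:
                out.extend(members)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, members in self.regions.items():
            for t in members:
                row = {"transcript": t, "region": key}
                for s in self.strains:
                    row[f"direction_{s}"] = self.directions[t].get(s, "")
                rows.append(row)
        return pd.DataFrame(rows).sort_values(["region", "transcript"]).reset_index(drop=True)


@dataclass
class ConcordanceSummary:
    """Direction agreement among the strains sharing a set of transcripts."""

    strains: tuple[str, ...]
    n_overlapping: int
    n_same_direction: int
    up: list[str]
    down: list[str]
    discordant: list[str]


def partition_calls(calls: pd.DataFrame, strains=None) -> OverlapPartition:
    """Partition passing calls into exclusive Venn regions.

    ``calls`` is the output of the pattern caller; only rows with
    ``passes`` true contribute.  Duplicate (transcript, strain) passing
    calls are an error.  Transcript lists are sorted for determinism.
    """
    passing = calls[calls["passes"]] if "passes" in calls.columns else calls
    if passing.duplicated(subset=["transcript", "strain"]).any():
        dups = passing[passing.duplicated(subset=["transcript", "strain"])]
        raise ValueError(
            f"duplicate (transcript, strain) calls: "
            f"{dups[['transcript', 'strain']].values[:3].tolist()}"
        )
    if strains is None:
        strains = tuple(pd.unique(calls["strain"]))
    else:
        strains = tuple(strains)
    directions: dict[str, dict[str, str]] = {}
    membership: dict[str, set[str]] = {}
    for row in passing.itertuples(index=False):
        membership.setdefault(row.transcript, set()).add(row.strain)
        directions.setdefault(row.transcript, {})[row.strain] = row.direction
    part = OverlapPartition(strains=strains, regions={}, directions=directions)
    keys = ["&".join(c) for r in range(1, len(strains) + 1)
            for c in _combinations(strains, r)]
    part.regions = {k: [] for k in keys}
    for transcript, members in membership.items():
        part.regions[part.region_key(members)].append(transcript)
    for k in part.regions:
        part.regions[k].sort()
    return part


def _combinations(items, r):
    from itertools import combinations

    return combinations(items, r)


def concordance(partition: OverlapPartition, strains) -> ConcordanceSummary:
    """Direction concordance over the inclusive overlap of two or three strains.

    A transcript counts as overlapping when it passes in *all* requested
    strains (inclusive of any larger region); it is concordant when its
    direction is identical in all of them.
    """
    strains = tuple(strains)
    unknown = set(strains) - set(partition.strains)
    if unknown:
        raise ValueError(f"unknown strain label(s): {sorted(unknown)}")
    up, down, discordant = [], [], []
    for transcript, dirs in partition.directions.items():
        if not set(strains) <= set(dirs):
            continue
        values = {dirs[s] for s in strains}
        if values == {"UP"}:
            up.append(transcript)
        elif values == {"DOWN"}:
            down.append(transcript)
        else:
            discordant.append(transcript)
    up.sort(), down.sort(), discordant.sort()
    n_overlap = len(up) + len(down) + len(discordant)
    return ConcordanceSummary(
        strains=strains,
        n_overlapping=n_overlap,
        n_same_direction=len(up) + len(down),
        up=up,
        down=down,
        discordant=discordant,
    )


def concordance_table(partition: OverlapPartition) -> pd.DataFrame:
    """Concordance summaries for all strain pairs and the full triple."""
    groups = list(_combinations(partition.strains, 2))
    if len(partition.strains) >= 3:
        groups += list(_combinations(partition.strains, len(partition.strains)))
    rows = []
    for g in groups:
        c = concordance(partition, g)
        rows.append(
            {
                "strains": "&".join(c.strains),
                "n_overlapping": c.n_overlapping,
                "n_same_direction": c.n_same_direction,
                "up": ";".join(c.up),
                "down": ";".join(c.down),
                "discordant": ";".join(c.discordant),
            }
        )
    return pd.DataFrame(rows)


def strain_contrasts(
    matrix: pd.DataFrame, samples: pd.DataFrame, transcripts, strains
) -> pd.DataFrame:
    """Per-strain signed log2 stress contrast (mean CMS-R - mean NH-R)."""
    missing = [t for t in transcripts if t not in matrix.index]
    if missing:
        raise ValueError(f"transcripts absent from matrix: {missing[:5]}")
    cols = {}
    for strain in strains:
        cmsr = samples.loc[
            (samples["strain"] == strain) & (samples["treatment"] == "CMS-R"), "sample_id"
        ]
        nhr = samples.loc[
            (samples["strain"] == strain) & (samples["treatment"] == "NH-R"), "sample_id"
        ]
        if cmsr.empty or nhr.empty:
            raise ValueError(f"strain {strain!r} lacks CMS-R or NH-R samples for contrast")
        sub = matrix.loc[list(transcripts)]
        cols[strain] = sub[list(cmsr)].mean(axis=1) - sub[list(nhr)].mean(axis=1)
    return pd.DataFrame(cols)


def cluster_overlap(
    matrix: pd.DataFrame, samples: pd.DataFrame, partition: OverlapPartition
) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage clustering of the multi-strain transcripts.

    Each shared transcript is represented by its per-strain contrast
    vector (one signed log2 value per strain).  Transcripts are sorted by
    id before linkage so ties and leaf order are deterministic.

    Returns ``(linkage_matrix, leaf_order, newick)``.
    """
    transcripts = partition.multi_strain_transcripts
    if len(transcripts) < 2:
        raise ValueError("need at least two shared transcripts to cluster")
    feats = strain_contrasts(matrix, samples, transcripts, partition.strains)
    Z = hierarchy.linkage(pdist(feats.to_numpy(), metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [transcripts[i] for i in leaves]
    newick = linkage_to_newick(Z, transcripts)
    return Z, leaf_order, newick


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"
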