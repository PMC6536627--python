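"""Hypergeometric over-representation analysis of gene sets.

A target list (e.g. the transcripts called stress-responsive in one
strain) is tested against a background universe for over-representation
of each category in a gene-set collection.  The p-value is the upper tail
of the hypergeometric distribution: the probability of drawing at least
the observed overlap when sampling ``|target|`` ids from ``|background|``
of which ``m`` belong to the category.  Categories smaller than the
minimum size (within the background) are excluded before testing, and
Benjamini–Hochberg correction runs over the tested categories only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .patterns import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene/transcript sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Read a GMT file (name <tab> description <tab> ids...)."""
        sets: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
                name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
                if name in sets:
                    raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
                sets[name] = set(members)
                descriptions[name] = desc
        return cls(sets=sets, descriptions=descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def ora(
    target,
    background,
    sets: GeneSetCollection,
    min_size: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis of ``target`` against ``background``.

    Returns a DataFrame sorted by p with columns category, set_size
    (within background), overlap, p, q, significant.  ``significant``
    requires q < alpha (the set-size floor is already enforced by the
    exclusion).  Raises if the target is not a subset of the background.
    """
    target = set(target)
    background = set(background)
    stray = target - background
    if stray:
        raise ValueError(f"target ids outside background: {sorted(stray)[:10]}")
    N, n = len(background), len(target)
    rows = []
    for name, members in sets.sets.items():
        in_bg = members & background
        m = len(in_bg)
        if m < min_size:
            continue
        k = len(in_bg & target)
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append({"category": name, "set_size": m, "overlap": k, "p": p})
    result = pd.DataFrame(rows, columns=["category", "set_size", "overlap", "p"])
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["q"] < alpha
    return result.sort_values(["p", "category"]).reset_index(drop=True)
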