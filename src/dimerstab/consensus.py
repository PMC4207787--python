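"""Consensus docking-rank aggregation.

Two docking engines with opposite score conventions (one higher-is-better
in roughly [4, 9], one lower-is-better in roughly [-9, -4]) score the same
compound universe against the same receptor conformation.  Compounds in
both engines' top-N lists form that conformation's consensus set; pooling
over conformations yields the candidate list with full provenance.  The
pooled result reports both the union size and the sum of per-conformation
counts, since overlapping conformations make the two differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "ConformationConsensus",
    "ConsensusResult",
    "rank",
    "top_n",
    "consensus",
    "pool_conformations",
    "read_score_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-engine, per-conformation docking scores for a compound universe."""

    engine: str
    conformation: str
    scores: pd.Series  # index: compound id, values: score
    direction: str  # "higher" | "lower"

    def __post_init__(self) -> None:
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        s = pd.Series(self.scores, dtype=float)
        if s.index.has_duplicates:
            raise ValueError("compound ids must be unique within a table")
        if not np.all(np.isfinite(s.to_numpy())):
            raise ValueError("scores must be finite")
        self.scores = s

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ConformationConsensus:
    conformation: str
    engines: tuple[str, str]
    compounds: set[str]
    per_engine_top: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class ConsensusResult:
    """Pooled candidates over all conformations, with provenance."""

    per_conformation: list[ConformationConsensus]
    union: set[str]
    count_sum: int  # sum of per-conformation consensus sizes (with overlap)
    provenance: pd.DataFrame  # compound_id, conformation, engine, score, rank

    @property
    def per_conformation_counts(self) -> dict[str, int]:
        return {c.conformation: len(c.compounds) for c in self.per_conformation}


def rank(table: ScoreTable) -> list[str]:
    """Compound ids sorted best-first by score, ties broken by id."""
    if len(table) == 0:
        raise ValueError("empty score table")
    ascending = table.direction == "lower"
    df = table.scores.rename("score").reset_index()
    df.columns = ["id", "score"]
    df = df.sort_values(["score", "id"], ascending=[ascending, True],
                        kind="mergesort")
    return df["id"].tolist()


def top_n(ranked: list[str], table: ScoreTable, n: int = 2000) -> set[str]:
    """The best *n* compounds; score ties across the cutoff boundary are all
    included (the set may then exceed *n*, which is logged)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n >= len(ranked):
        return set(ranked)
    boundary_score = table.scores[ranked[n - 1]]
    cut = n
    while cut < len(ranked) and table.scores[ranked[cut]] == boundary_score:
        cut += 1
    if cut > n:
        logger.warning(
            "top_n(%s/%s): boundary tie at score %s extends the set from "
            "%d to %d compounds", table.engine, table.conformation,
            boundary_score, n, cut)
    return set(ranked[:cut])


def consensus(
    set_a: set[str], set_b: set[str],
    engine_a: str = "A", engine_b: str = "B",
) -> set[str]:
    """Intersection of two engines' top sets for one conformation."""
    if engine_a == engine_b:
        raise ValueError(
            "consensus requires two different engines, got "
            f"{engine_a!r} twice")
    return set_a & set_b


def consensus_for_conformation(
    table_a: ScoreTable, table_b: ScoreTable, n: int = 2000
) -> ConformationConsensus:
    """Rank both tables, take each top-N and intersect."""
    if table_a.conformation != table_b.conformation:
        raise ValueError("tables are for different conformations")
    if set(table_a.scores.index) != set(table_b.scores.index):
        raise ValueError(
            "engines scored different compound universes for conformation "
            f"{table_a.conformation!r}")
    top_a = top_n(rank(table_a), table_a, n)
    top_b = top_n(rank(table_b), table_b, n)
    common = consensus(top_a, top_b, table_a.engine, table_b.engine)
    return ConformationConsensus(
        conformation=table_a.conformation,
        engines=(table_a.engine, table_b.engine),
        compounds=common,
        per_engine_top={table_a.engine: top_a, table_b.engine: top_b},
    )


def pool_conformations(
    results: list[ConformationConsensus],
    tables: list[ScoreTable] | None = None,
) -> ConsensusResult:
    """Union of the per-conformation consensus sets with provenance.

    Both the union size and the sum of the per-conformation counts are
    surfaced: a compound found at several conformations inflates the sum
    but not the union.
    """
    if not results:
        raise ValueError("need at least one conformation result")
    union: set[str] = set()
    count_sum = 0
    for res in results:
        union |= res.compounds
        count_sum += len(res.compounds)
    rows = []
    table_map = {}
    if tables:
        for t in tables:
            ranked = rank(t)
            pos = {cid: i + 1 for i, cid in enumerate(ranked)}
            table_map[(t.conformation, t.engine)] = (t, pos)
    for res in results:
        for cid in sorted(res.compounds):
            for engine in res.engines:
                key = (res.conformation, engine)
                if key in table_map:
                    t, pos = table_map[key]
                    rows.append({
                        "compound_id": cid,
                        "conformation": res.conformation,
                        "engine": engine,
                        "score": float(t.scores[cid]),
                        "rank": pos[cid],
                    })
                else:
                    rows.append({"compound_id": cid,
                                 "conformation": res.conformation,
                                 "engine": engine,
                                 "score": float("nan"), "rank": -1})
    prov = pd.DataFrame(
        rows, columns=["compound_id", "conformation", "engine",
                       "score", "rank"])
    return ConsensusResult(per_conformation=results, union=union,
                           count_sum=count_sum, provenance=prov)


def read_score_table(path: str | Path) -> list[ScoreTable]:
    """Read CSV with columns engine, conformation, compound_id, score and an
    optional direction column ('higher'/'lower'; inferred from the score
    sign convention if absent: all-negative scores are lower-is-better)."""
    df = pd.read_csv(path)
    required = {"engine", "conformation", "compound_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score CSV missing columns {sorted(missing)}")
    tables = []
    for (engine, conf), grp in df.groupby(["engine", "conformation"],
                                          sort=True):
        if "direction" in grp.columns:
            direction = str(grp["direction"].iloc[0])
        else:
            direction = "lower" if (grp["score"] < 0).all() else "higher"
        tables.append(ScoreTable(
            engine=str(engine), conformation=str(conf),
            scores=pd.Series(grp["score"].to_numpy(),
                             index=grp["compound_id"].astype(str)),
            direction=direction))
    return tables
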