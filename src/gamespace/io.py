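"""Tabular exporters: per-game census, edge lists and trajectory logs.

Every file starts with ``#``-prefixed metadata lines embedding the
package version and the configuration (seed, command) needed to
regenerate it, followed by an ordinary CSV body; read them back with
``pandas.read_csv(path, comment="#")``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .dynamics import TrajectoryRecord, attractor_set, game_features, is_attractor
from .equilibria import pure_nash_count
from .games import OrdinalGame, game_to_json, is_win_win, neighbors

__all__ = [
    "space_table",
    "edge_table",
    "attractor_table",
    "trajectory_table",
    "write_csv",
]


def write_csv(df: pd.DataFrame, path: str | Path, config: Optional[Mapping] = None) -> None:
    """Write a CSV with regeneration metadata in leading comment lines."""
    path = Path(path)
    lines = [f"# gamespace v{__version__}"]
    for key, value in (config or {}).items():
        lines.append(f"# {key}={value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def _game_ids(space: Sequence[OrdinalGame]) -> dict[OrdinalGame, int]:
    return {g: i for i, g in enumerate(space)}


def space_table(space: Sequence[OrdinalGame]) -> pd.DataFrame:
    """Per-game properties of an enumerated space.

    Columns: id, serialized ranks, win–win flag, pure-Nash count, and
    the attractor flag for each focal player.
    """
    rows = []
    for i, g in enumerate(space):
        rows.append(
            {
                "id": i,
                "ranks": game_to_json(g),
                "win_win": is_win_win(g),
                "pure_nash_count": pure_nash_count(g),
                **{
                    f"attractor_focal{j}": is_attractor(g, j)
                    for j in range(g.n_players)
                },
            }
        )
    return pd.DataFrame(rows)


def edge_table(space: Sequence[OrdinalGame]) -> pd.DataFrame:
    """Undirected neighbour edge list (game_id_a < game_id_b)."""
    ids = _game_ids(space)
    edges = set()
    for g in space:
        for h in neighbors(g):
            if h in ids:
                a, b = sorted((ids[g], ids[h]))
                edges.add((a, b))
    return pd.DataFrame(sorted(edges), columns=["game_id_a", "game_id_b"])


def attractor_table(space: Sequence[OrdinalGame], focal: int) -> pd.DataFrame:
    """Attractor report: game id, focal, win–win flag, basin component id."""
    ids = _game_ids(space)
    report = attractor_set(space, focal)
    component_of = {}
    for c, comp in enumerate(sorted(report.basin_components, key=len, reverse=True)):
        for g in comp:
            component_of[g] = c
    rows = [
        {
            "game_id": ids[g],
            "focal": focal,
            "win_win": is_win_win(g),
            "component_id": component_of[g],
        }
        for g in report.attractors
    ]
    return pd.DataFrame(sorted(rows, key=lambda r: r["game_id"]))


def trajectory_table(
    record: TrajectoryRecord, space: Optional[Sequence[OrdinalGame]] = None
) -> pd.DataFrame:
    """One row per visited game: step, id/ranks, focal, features, seed."""
    ids = _game_ids(space) if space is not None else {}
    rows = []
    for step, g in enumerate(record.games):
        fv = game_features(g, record.focal)
        rows.append(
            {
                "step": step,
                "game_id": ids.get(g, -1),
                "ranks": game_to_json(g),
                "focal": record.focal,
                "stable": fv.stable,
                "predictable": fv.predictable,
                "efficient": fv.efficient,
                "seed": record.seed,
            }
        )
    return pd.DataFrame(rows)
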