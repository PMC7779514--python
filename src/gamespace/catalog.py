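"""Packaged catalog of named two-player games."""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .games import GameError, OrdinalGame, make_game

__all__ = ["GameCatalogEntry", "load_catalog", "get_game", "game_names"]


@dataclass(frozen=True)
class GameCatalogEntry:
    name: str
    game: OrdinalGame
    notes: str = ""


@lru_cache(maxsize=1)
def load_catalog() -> dict[str, GameCatalogEntry]:
    """Load the packaged named-game catalog, keyed by unique name."""
    text = resources.files("gamespace.data").joinpath("catalog.json").read_text()
    raw = json.loads(text)
    catalog: dict[str, GameCatalogEntry] = {}
    for record in raw["games"]:
        name = record["name"]
        if name in catalog:
            raise GameError(f"duplicate catalog name {name!r}")
        catalog[name] = GameCatalogEntry(
            name=name,
            game=make_game(record["n_players"], record["ranks"]),
            notes=record.get("notes", ""),
        )
    return catalog


def get_game(name: str) -> OrdinalGame:
    """Look up a named game; raises ``KeyError`` with suggestions if unknown."""
    catalog = load_catalog()
    if name not in catalog:
        raise KeyError(f"unknown game {name!r}; available: {', '.join(sorted(catalog))}")
    return catalog[name].game


def game_names() -> list[str]:
    return sorted(load_catalog())
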