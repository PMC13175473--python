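"""Shared gene universe: a stable bijection between symbols and indices."""

from __future__ import annotations

from collections.abc import Iterable, Sequence


class GeneUniverse:
    """Ordered set of unique gene symbols with integer indices.

    The ordering is the input ordering, so the symbol -> index map is stable
    across runs given identical input.
    """

    def __init__(self, symbols: Sequence[str]):
        seen = set()
        ordered = []
        for s in symbols:
            if s in seen:
                raise ValueError(f"duplicate gene symbol: {s!r}")
            seen.add(s)
            ordered.append(s)
        if not ordered:
            raise ValueError("empty gene universe")
        self.symbols: list[str] = ordered
        self.index: dict[str, int] = {s: i for i, s in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index

    def __iter__(self):
        return iter(self.symbols)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneUniverse) and self.symbols == other.symbols

    def indices_of(self, symbols: Iterable[str]) -> list[int]:
        return [self.index[s] for s in symbols]
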