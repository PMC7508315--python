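"""Message pools: interchangeable phrasings selected without tedious repetition.

A pool groups message variants (health tips, prompt phrasings, intervention
texts) into named subsets.  Selection is *shuffled-cycle*: each patient works
through a random permutation of the whole pool, so within one cycle no
message repeats, and when the cycle resets the first message of the new cycle
is never the last message of the old one (pool size permitting).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union


class PoolError(ValueError):
    """Raised for malformed pool files or empty pools."""


@dataclass
class MessagePool:
    pool_id: str
    subsets: Dict[str, List[str]]
    # per-patient cycle state: remaining message indices + last index sent
    _cycles: Dict[str, List[int]] = field(default_factory=dict, repr=False)
    _last: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, messages in self.subsets.items():
            if not messages:
                raise PoolError(f"pool {self.pool_id!r}: subset {name!r} is empty")
            if len(set(messages)) != len(messages):
                raise PoolError(f"pool {self.pool_id!r}: duplicate message in subset {name!r}")
        if not self.subsets:
            raise PoolError(f"pool {self.pool_id!r} declares no subsets")

    @property
    def messages(self) -> List[str]:
        """All messages, flattened in subset order."""
        return [m for msgs in self.subsets.values() for m in msgs]

    def __len__(self) -> int:
        return sum(len(m) for m in self.subsets.values())


def select(pool: MessagePool, patient_id: str, rng: random.Random) -> str:
    """Draw the next message of *patient_id*'s shuffled cycle.

    Uniformly random over the messages not yet sent in the current cycle;
    when the cycle is exhausted it reshuffles, avoiding an immediate repeat
    of the last message whenever the pool holds more than one message.
    """
    n = len(pool)
    if n == 0:
        raise PoolError(f"pool {pool.pool_id!r} is empty")
    remaining = pool._cycles.get(patient_id)
    if not remaining:
        remaining = list(range(n))
        rng.shuffle(remaining)
        last = pool._last.get(patient_id)
        # cycle boundary: never start the new cycle with the previous message
        if n > 1 and last is not None and remaining[-1] == last:
            j = rng.randrange(n - 1)
            remaining[-1], remaining[j] = remaining[j], remaining[-1]
        pool._cycles[patient_id] = remaining
    idx = remaining.pop()
    pool._last[patient_id] = idx
    return pool.messages[idx]


def load_pool(source: Union[str, Path], pool_id: str | None = None) -> MessagePool:
    """Load a pool from a UTF-8 text file.

    Format: ``[subset-name]`` section headers, one message per line; blank
    lines and ``#`` comment lines ignored.  Empty subsets and duplicated
    messages within a subset are load errors naming the subset.
    """
    path = Path(source)
    subsets: Dict[str, List[str]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            if not current:
                raise PoolError(f"{path}:{lineno}: empty subset name")
            if current in subsets:
                raise PoolError(f"{path}:{lineno}: duplicate subset {current!r}")
            subsets[current] = []
        else:
            if current is None:
                raise PoolError(f"{path}:{lineno}: message before any [subset] header")
            subsets[current].append(line)
    return MessagePool(pool_id=pool_id or path.stem, subsets=subsets)


def shipped_tip_pool() -> MessagePool:
    """The shipped synthetic health-tip pool (11 subsets, 54 messages)."""
    from importlib import resources

    path = Path(resources.files("txtpro").joinpath("data", "pools", "health_tips.txt"))
    return load_pool(path, pool_id="health_tips")
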