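"""Recruitment forests: seed-rooted trees of who-recruited-whom.

A recruitment forest records, for every submission, its recruiter (``None``
for seeds), its wave number (seeds are wave 0, a recruit's wave is its
recruiter's wave plus one) and its submission time.  RDS chain diagnostics
(wave counts, chain sizes, transition matrices) all read this structure.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field


@dataclass
class RecruitmentForest:
    """Seed-rooted recruitment trees.

    Parameters
    ----------
    parent
        Maps each node id to its recruiter's id, or ``None`` for seeds.
    wave
        Wave number per node; seeds are 0.
    timestamp
        Submission time per node, in days since the study start.  Times
        increase strictly along every chain.
    person
        Maps a node (submission) id to the underlying individual id.  With
        replacement-free recruitment this is the identity and may be omitted.
    """

    parent: dict
    wave: dict = field(default_factory=dict)
    timestamp: dict = field(default_factory=dict)
    person: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.wave:
            self.wave = self._compute_waves()
        if not self.person:
            self.person = {v: v for v in self.parent}
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def nodes(self) -> list:
        return list(self.parent)

    @property
    def seeds(self) -> list:
        return [v for v, p in self.parent.items() if p is None]

    def children(self) -> dict:
        ch: dict = {v: [] for v in self.parent}
        for v, p in self.parent.items():
            if p is not None:
                ch[p].append(v)
        return ch

    def root_of(self, node):
        """Chain id: the seed at the root of ``node``'s chain."""
        seen = set()
        while self.parent[node] is not None:
            if node in seen:
                raise ValueError(f"cycle detected at node {node!r}")
            seen.add(node)
            node = self.parent[node]
        return node

    def _compute_waves(self) -> dict:
        waves: dict = {}
        ch: dict = {v: [] for v in self.parent}
        roots = []
        for v, p in self.parent.items():
            if p is None:
                roots.append(v)
            else:
                if p not in self.parent:
                    raise ValueError(f"recruiter {p!r} of {v!r} not in forest")
                ch[p].append(v)
        queue = deque((r, 0) for r in roots)
        while queue:
            v, w = queue.popleft()
            waves[v] = w
            for c in ch[v]:
                queue.append((c, w + 1))
        if len(waves) != len(self.parent):
            orphans = sorted(set(self.parent) - set(waves), key=repr)[:5]
            raise ValueError(f"nodes unreachable from any seed (cycle?): {orphans}")
        return waves

    def validate(self) -> None:
        """Check acyclicity, wave consistency and reachability from seeds."""
        recomputed = self._compute_waves()
        for v, w in recomputed.items():
            if self.wave[v] != w:
                raise ValueError(
                    f"wave inconsistency at {v!r}: stored {self.wave[v]}, "
                    f"parent map implies {w}"
                )

    def recruitment_events(self) -> list:
        """(recruiter, recruit) pairs, one per non-seed node."""
        return [(p, v) for v, p in self.parent.items() if p is not None]

    def __len__(self) -> int:
        return len(self.parent)
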