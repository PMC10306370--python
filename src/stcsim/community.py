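"""Community state: interaction matrix, fitnesses, per-island abundances, registry.

The ``Community`` arrays hold only the extant strains (rows/columns are
compacted whenever global extinctions are flushed); the ``StrainRegistry``
keeps a permanent record of every strain ever introduced.  Global
extinctions are irreversible: a dead strain is never reintroduced.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .sampling import InvaderDraw


class EmptyCommunityError(RuntimeError):
    """Raised when an operation requires at least one extant strain."""


@dataclass
class StrainRecord:
    id: int
    parent_id: int | None
    s: float
    birth_epoch: int
    death_epoch: int | None = None

    @property
    def alive(self) -> bool:
        return self.death_epoch is None


@dataclass
class StrainRegistry:
    """Permanent per-strain bookkeeping (dead strains are never resurrected)."""

    records: dict = field(default_factory=dict)
    _next_id: int = 0

    def new_strain(
        self, s: float, parent_id: int | None = None, birth_epoch: int = 0
    ) -> int:
        sid = self._next_id
        self._next_id += 1
        self.records[sid] = StrainRecord(
            id=sid, parent_id=parent_id, s=float(s), birth_epoch=int(birth_epoch)
        )
        return sid

    def mark_dead(self, sid: int, epoch: int) -> None:
        rec = self.records[sid]
        if rec.death_epoch is not None:
            raise RuntimeError(
                f"strain {sid} already died at epoch {rec.death_epoch}; "
                "extinctions are permanent"
            )
        rec.death_epoch = int(epoch)

    def is_alive(self, sid: int) -> bool:
        return self.records[sid].alive

    def to_dict(self) -> dict:
        return {
            "next_id": self._next_id,
            "records": [dataclasses.asdict(r) for r in self.records.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StrainRegistry":
        reg = cls(_next_id=int(d["next_id"]))
        for r in d["records"]:
            reg.records[int(r["id"])] = StrainRecord(
                id=int(r["id"]),
                parent_id=None if r["parent_id"] is None else int(r["parent_id"]),
                s=float(r["s"]),
                birth_epoch=int(r["birth_epoch"]),
                death_epoch=(
                    None if r["death_epoch"] is None else int(r["death_epoch"])
                ),
            )
        return reg


@dataclass
class Community:
    """Extant-strain state of the metacommunity.

    ``nu`` has shape (L, I): fractional abundance of strain row i on island
    alpha; each column sums to one.  ``ids[i]`` is the registry id of row i.
    ``migration`` optionally overrides the scalar rate per strain (used by
    the decay-based bias estimator which switches migration off for one
    strain); ``None`` means the uniform rate ``params.m``.
    """

    params: ModelParams
    V: np.ndarray
    s: np.ndarray
    nu: np.ndarray
    ids: np.ndarray
    registry: StrainRegistry
    t: float = 0.0
    migration: np.ndarray | None = None

    @property
    def L(self) -> int:
        """Number of extant strains."""
        return int(self.nu.shape[0])

    @property
    def n_islands(self) -> int:
        return int(self.nu.shape[1])

    @property
    def nu_bar(self) -> np.ndarray:
        """Instantaneous across-island mean abundance of each strain."""
        return self.nu.mean(axis=1)

    def migration_rates(self) -> np.ndarray:
        if self.migration is not None:
            return self.migration
        return np.full(self.L, self.params.m)

    def copy(self) -> "Community":
        return Community(
            params=self.params,
            V=self.V.copy(),
            s=self.s.copy(),
            nu=self.nu.copy(),
            ids=self.ids.copy(),
            registry=StrainRegistry.from_dict(self.registry.to_dict()),
            t=self.t,
            migration=None if self.migration is None else self.migration.copy(),
        )

    def index_of(self, sid: int) -> int:
        hits = np.flatnonzero(self.ids == sid)
        if hits.size == 0:
            raise KeyError(f"strain {sid} is not extant")
        return int(hits[0])

    def append_strain(self, draw: InvaderDraw, sid: int) -> None:
        """Grow the arrays by one strain (abundance row initialised to zero)."""
        L = self.L
        V_new = np.empty((L + 1, L + 1))
        V_new[:L, :L] = self.V
        V_new[L, :L] = draw.row
        V_new[:L, L] = draw.col
        V_new[L, L] = draw.self_interaction
        self.V = V_new
        self.s = np.append(self.s, draw.s)
        self.nu = np.vstack([self.nu, np.zeros((1, self.n_islands))])
        self.ids = np.append(self.ids, sid)
        if self.migration is not None:
            self.migration = np.append(self.migration, self.params.m)

    def drop_rows(self, rows: np.ndarray) -> None:
        keep = np.setdiff1d(np.arange(self.L), rows)
        self.V = self.V[np.ix_(keep, keep)]
        self.s = self.s[keep]
        self.nu = self.nu[keep]
        self.ids = self.ids[keep]
        if self.migration is not None:
            self.migration = self.migration[keep]

    def flush_global_extinctions(self, epoch: int) -> list[int]:
        """Remove strains with zero abundance on every island; returns their ids.

        The removed strains are marked dead in the registry (permanently).
        """
        dead_rows = np.flatnonzero((self.nu <= 0).all(axis=1))
        dead_ids = [int(self.ids[r]) for r in dead_rows]
        for sid in dead_ids:
            self.registry.mark_dead(sid, epoch)
        if dead_rows.size:
            self.drop_rows(dead_rows)
        return dead_ids

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "V": self.V.tolist(),
            "s": self.s.tolist(),
            "nu": self.nu.tolist(),
            "ids": self.ids.tolist(),
            "t": self.t,
            "registry": self.registry.to_dict(),
            "migration": None if self.migration is None else self.migration.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Community":
        return cls(
            params=ModelParams.from_dict(d["params"]),
            V=np.asarray(d["V"], dtype=float),
            s=np.asarray(d["s"], dtype=float),
            nu=np.asarray(d["nu"], dtype=float),
            ids=np.asarray(d["ids"], dtype=int),
            registry=StrainRegistry.from_dict(d["registry"]),
            t=float(d["t"]),
            migration=(
                None
                if d.get("migration") is None
                else np.asarray(d["migration"], dtype=float)
            ),
        )
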