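"""Pedigree structures, recursive kinship coefficients, and unrelated-subset extraction.

The kinship coefficient psi(i, i') is the probability that an allele drawn at
random from individual i and one drawn from i' are identical by descent.  Twice
psi is the expected genetic correlation used by the polygenic covariance in the
mixed models: Cov(g_i, g_i') = 2 psi sigma_g^2.  Kinship is computed from the
pedigree alone by the classical recursion (founders unrelated and non-inbred by
assumption), giving a block-diagonal matrix with one block per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "read_pedigree",
    "compute_kinship",
    "extract_unrelated",
]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (missing parents, cycles, duplicates)."""


@dataclass(frozen=True)
class Pedigree:
    """A set of pedigree members in file order.

    ``members`` has columns ``fid, iid, father, mother, sex``; ``father`` and
    ``mother`` are ``None`` for founders.  Each member has either both parents
    present in the same family or both missing.
    """

    members: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.members
        expected = ["fid", "iid", "father", "mother", "sex"]
        if list(m.columns[:5]) != expected:
            raise PedigreeError(f"member table must have columns {expected}")
        dup = m.duplicated(subset=["fid", "iid"])
        if dup.any():
            bad = m.loc[dup, ["fid", "iid"]].iloc[0]
            raise PedigreeError(
                f"duplicated individual {bad.iid!r} within family {bad.fid!r}"
            )
        for fid, fam in m.groupby("fid", sort=False):
            ids = set(fam["iid"])
            for row in fam.itertuples():
                parents = (row.father, row.mother)
                if (parents[0] is None) != (parents[1] is None):
                    raise PedigreeError(
                        f"individual {row.iid!r} in family {fid!r} has exactly one "
                        "recorded parent; founders need both missing"
                    )
                for par in parents:
                    if par is not None and par not in ids:
                        raise PedigreeError(
                            f"individual {row.iid!r} in family {fid!r} references "
                            f"absent parent {par!r}"
                        )
        # acyclicity is checked by the topological sort; run it once up front
        for fid, fam in m.groupby("fid", sort=False):
            _topological_order(fam)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def family_ids(self) -> list:
        """Family ids in order of first appearance."""
        return list(self.members["fid"].drop_duplicates())

    def founders(self) -> pd.DataFrame:
        mask = [f is None for f in self.members["father"]]
        return self.members[mask]


def _topological_order(fam: pd.DataFrame) -> list[int]:
    """Indices of one family's members, parents before children.

    Raises :class:`PedigreeError` on a cyclic parent graph.
    """
    idx_of = {row.iid: i for i, row in enumerate(fam.itertuples())}
    rows = list(fam.itertuples())
    done: set[int] = set()
    order: list[int] = []
    # Kahn-style sweep; bounded number of passes on an acyclic graph
    remaining = set(range(len(rows)))
    while remaining:
        progressed = False
        for i in sorted(remaining):
            row = rows[i]
            if row.father is None or (
                idx_of[row.father] in done and idx_of[row.mother] in done
            ):
                order.append(i)
                done.add(i)
                remaining.discard(i)
                progressed = True
        if not progressed:
            cyc = [rows[i].iid for i in sorted(remaining)]
            raise PedigreeError(f"cyclic parent graph involving {cyc}")
    return order


def read_pedigree(path) -> Pedigree:
    """Read a PLINK FAM-dialect pedigree file.

    Whitespace/tab separated columns: family, individual, father, mother, sex
    (1=male, 2=female, 0=unknown) and an optional phenotype placeholder.
    A parent id of ``"0"`` means missing.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >= 5 whitespace-separated fields"
                )
            fid, iid, fa, mo, sex = parts[:5]
            rows.append(
                dict(
                    fid=fid,
                    iid=iid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=_SEX_CODES.get(sex, "unknown"),
                )
            )
    members = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex"]
    ).astype(object)
    return Pedigree(members=members)


@dataclass(frozen=True)
class KinshipMatrix:
    """Pedigree kinship coefficients, family-major order, block-diagonal by family.

    ``psi[i, j]`` is the kinship coefficient between ``subject_ids[i]`` and
    ``subject_ids[j]``; the diagonal is 0.5 for non-inbred individuals.
    """

    subject_ids: list
    family_ids: np.ndarray
    psi: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.subject_ids)}
        )

    def index_of(self, subject_id) -> int:
        return self._index[subject_id]

    def submatrix(self, subject_ids) -> np.ndarray:
        ix = [self._index[s] for s in subject_ids]
        return self.psi[np.ix_(ix, ix)]

    def relatedness(self, subject_ids) -> np.ndarray:
        """2*psi on the given subjects — the polygenic correlation matrix."""
        return 2.0 * self.submatrix(subject_ids)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship coefficients by the classical recursion.

    For non-founder i with parents f, m processed after j (j not a descendant
    of i): psi(i, j) = (psi(f, j) + psi(m, j)) / 2 and
    psi(i, i) = (1 + psi(f, m)) / 2.  Founders are unrelated and non-inbred.
    Subjects are ordered family-major, file order within family.
    """
    members = ped.members
    subject_ids: list = []
    fam_of: list = []
    blocks: list[np.ndarray] = []
    for fid, fam in members.groupby("fid", sort=False):
        order = _topological_order(fam)
        rows = list(fam.itertuples())
        n = len(rows)
        psi = np.zeros((n, n))
        local = {rows[i].iid: None for i in range(n)}  # iid -> topo slot
        done: list[int] = []
        for slot, i in enumerate(order):
            row = rows[i]
            local[row.iid] = slot
            if row.father is None:
                psi[slot, slot] = 0.5
            else:
                f, m = local[row.father], local[row.mother]
                psi[slot, slot] = 0.5 * (1.0 + psi[f, m])
                for j in done:
                    v = 0.5 * (psi[f, j] + psi[m, j])
                    psi[slot, j] = psi[j, slot] = v
            done.append(slot)
        # back to file order within the family
        inv = np.empty(n, dtype=int)
        for slot, i in enumerate(order):
            inv[i] = slot
        psi = psi[np.ix_(inv, inv)]
        blocks.append(psi)
        subject_ids.extend(r.iid for r in rows)
        fam_of.extend([fid] * n)

    if len(set(subject_ids)) != len(subject_ids):
        seen, dups = set(), set()
        for s in subject_ids:
            (dups if s in seen else seen).add(s)
        raise PedigreeError(
            f"individual ids must be globally unique to key the kinship matrix; "
            f"duplicated across families: {sorted(dups)}"
        )

    n_total = len(subject_ids)
    psi_full = np.zeros((n_total, n_total))
    offset = 0
    for b in blocks:
        k = b.shape[0]
        psi_full[offset : offset + k, offset : offset + k] = b
        offset += k
    return KinshipMatrix(
        subject_ids=subject_ids, family_ids=np.asarray(fam_of, dtype=object), psi=psi_full
    )


def extract_unrelated(ped: Pedigree, km: KinshipMatrix) -> list:
    """Greedy maximal zero-kinship subset: founders in file order, then any
    remaining individual unrelated to everyone already selected.

    Deterministic given input order; idempotent on its own output.
    """
    selected: list = []
    sel_ix: list[int] = []
    founder = {r.iid: r.father is None for r in ped.members.itertuples()}
    for iid in (r.iid for r in ped.members.itertuples()):
        if founder[iid]:
            selected.append(iid)
            sel_ix.append(km.index_of(iid))
    for iid in (r.iid for r in ped.members.itertuples()):
        if founder[iid]:
            continue
        i = km.index_of(iid)
        if not sel_ix or np.all(km.psi[i, sel_ix] == 0.0):
            selected.append(iid)
            sel_ix.append(i)
    return selected
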