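"""Stage 3 — household co-generation by Gibbs sampling over the conditional tree.

Each zone's population total is first integerized into household counts by size, then
all members of all households are co-generated: household type, roles and genders are
fixed structurally, and the free attributes (age class, main activity, SPC, education,
household income class, car ownership) are resampled from their full conditional
distributions in a fixed sweep order.  Structural rules (head minimum age, spouse
gender complement, under-18 schoolchildren, retirement SPC, mother-child age gap) are
enforced as hard support restrictions of the sampled joint, not as post-hoc edits,
except for the mother-child gap which operates on integer ages after the class-level
chain has converged.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .conditionals import ConditionalError, ConditionalTable
from .schema import (
    AttributeSchema,
    SPC_INACTIVE,
    SPC_RETIRED,
    age_class_interval,
    compatible_household_types,
    default_schema,
    roles_for,
)

__all__ = [
    "GenerationConfig",
    "ConstraintError",
    "Individual",
    "Household",
    "Population",
    "CompiledModel",
    "integerize_household_counts",
    "gibbs_sweep",
    "generate_household",
    "generate_zone_population",
    "sample_age_within_class",
    "zone_rng",
    "validate_population",
    "REQUIRED_CPTS",
]

#: (target, conditioning) pairs the generator needs
REQUIRED_CPTS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("household_type", ("household_size",)),
    ("income_class", ("household_type",)),
    ("car_ownership", ("household_type", "income_class")),
    ("gender", ("role", "household_type")),
    ("age_class", ("household_type", "role")),
    ("main_activity", ("age_class",)),
    ("spc", ("age_class", "main_activity")),
    ("education", ("age_class", "spc")),
)

#: fixed systematic-scan order of the free attributes
SWEEP_ORDER_INDIVIDUAL = ("age_class", "main_activity", "spc", "education")
SWEEP_ORDER_HOUSEHOLD = ("income_class", "car_ownership")


class ConstraintError(ValueError):
    """A structural constraint leaves no feasible value."""


@dataclass
class GenerationConfig:
    """Tunable generation parameters.

    burn_in:
        Gibbs sweeps discarded before the household state is retained.
    head_min_age_multi / head_min_age_single:
        Minimum integer age of the household head in multi-person / one-person
        households (years).
    mother_child_gap:
        Minimum age difference between a mother and her eldest child (years).
    master_seed:
        Single seed from which per-zone substreams are derived.
    """

    burn_in: int = 20
    head_min_age_multi: int = 21
    head_min_age_single: int = 18
    mother_child_gap: int = 15
    master_seed: int = 0


def zone_rng(master_seed: int, zone_id: str) -> np.random.Generator:
    """Per-zone random substream, independent of zone processing order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(str(zone_id).encode())])
    )


# ---------------------------------------------------------------------------------
# agent records
# ---------------------------------------------------------------------------------

@dataclass
class Individual:
    individual_id: str
    household_id: str
    role: str
    age: int
    age_class: str
    gender: str
    spc: int
    education: str
    main_activity: str
    income: float | None = None
    overweight: int | None = None


@dataclass
class Household:
    household_id: str
    zone_id: str
    size: int
    household_type: str
    income_class: str
    car_ownership: int
    members: list[Individual] = field(default_factory=list)
    income: float | None = None


@dataclass
class Population:
    """Generated population as two aligned tables (households, individuals)."""

    households: pd.DataFrame
    individuals: pd.DataFrame

    def __len__(self) -> int:
        return len(self.households)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def merged(self) -> pd.DataFrame:
        """Individuals with household attributes broadcast onto members."""
        hh = self.households.drop(columns=["zone_id"], errors="ignore")
        return self.individuals.merge(hh, on="household_id", how="left")

    @staticmethod
    def concat(parts: Sequence["Population"]) -> "Population":
        return Population(
            pd.concat([p.households for p in parts], ignore_index=True),
            pd.concat([p.individuals for p in parts], ignore_index=True),
        )


# ---------------------------------------------------------------------------------
# integerization of household counts
# ---------------------------------------------------------------------------------

def integerize_household_counts(
    zone_population: int, size_probs: Sequence[float]
) -> np.ndarray:
    """Integer household counts h_1..h_6 whose sizes sum to the zone population.

    Among exact solutions, minimizes sum_s |h_s - E_s| where E_s is the expected
    household count N * p_s / mean-size; ties break to the lexicographically
    smallest (h_1, ..., h_6).  When no exact solution exists over the sizes with
    positive probability, totals within one individual are accepted, preferring
    undershoot.
    """
    n = int(zone_population)
    if n < 0:
        raise ValueError(f"negative zone population {zone_population}")
    p = np.asarray(size_probs, dtype=float)
    if p.shape != (6,):
        raise ValueError("size_probs must have 6 entries (sizes 1..6)")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("size_probs must be a probability vector")
    if n == 0:
        return np.zeros(6, dtype=int)

    sizes = [s for s in range(1, 7) if p[s - 1] > 0]
    if not sizes:
        raise ValueError("size_probs has no positive entry")
    mean_size = float(sum(s * p[s - 1] for s in sizes))
    expected = {s: n * p[s - 1] / mean_size for s in sizes}
    base = {s: int(math.floor(expected[s])) for s in sizes}

    # Proximity bound: an optimal integer solution lies within a bounded window of
    # the continuous optimum, so a small delta range around floor(E_s) suffices.
    window = 42

    def solve(total: int) -> np.ndarray | None:
        residual = total - sum(s * base[s] for s in sizes)
        # dp over partial weighted delta sums; value = (cost, h-vector prefix)
        dp: dict[int, tuple[float, tuple[int, ...]]] = {0: (0.0, ())}
        for s in sizes:
            lo = -min(base[s], window)
            hi = window
            nxt: dict[int, tuple[float, tuple[int, ...]]] = {}
            for t, (cost, vec) in dp.items():
                for d in range(lo, hi + 1):
                    h = base[s] + d
                    t2 = t + s * d
                    if abs(t2 - residual) > 6 * window:
                        continue
                    cand = (cost + abs(h - expected[s]), vec + (h,))
                    cur = nxt.get(t2)
                    if cur is None or cand < cur:
                        nxt[t2] = cand
            dp = nxt
        if residual not in dp:
            return None
        _, vec = dp[residual]
        out = np.zeros(6, dtype=int)
        for s, h in zip(sizes, vec):
            out[s - 1] = h
        return out

    for total in (n, n - 1, n + 1):
        if total < 0:
            continue
        sol = solve(total)
        if sol is not None:
            return sol
    raise ConstraintError(
        f"no household size vector over sizes {sizes} reaches population {n} +/- 1"
    )


# ---------------------------------------------------------------------------------
# compiled conditional model
# ---------------------------------------------------------------------------------

class _CompiledCpt:
    """Dense array view of a ConditionalTable for vectorized sampling."""

    def __init__(self, table: ConditionalTable, categories: dict[str, tuple]):
        self.target = table.target
        self.given = table.given
        self.categories = tuple(table.categories)
        self.given_cats = tuple(tuple(categories[g]) for g in table.given)
        cards = [len(c) for c in self.given_cats]
        rows = int(np.prod(cards)) if cards else 1
        self.array = np.zeros((rows, len(self.categories)), dtype=float)
        self.valid = np.zeros(rows, dtype=bool)
        self._strides = np.array(
            [int(np.prod(cards[i + 1:])) for i in range(len(cards))], dtype=np.int64
        )
        self._cards = cards
        for key, cell in table.cells.items():
            idx = 0
            for v, cats, stride in zip(key, self.given_cats, self._strides):
                idx += cats.index(v) * int(stride)
            self.array[idx] = cell.probs
            self.valid[idx] = True
        self._marginal = table.marginal() if table.cells else None

    def rows(self, parent_codes: list[np.ndarray]) -> np.ndarray:
        if not parent_codes:
            return np.zeros(1, dtype=np.int64)
        idx = np.zeros(len(parent_codes[0]), dtype=np.int64)
        for codes, stride in zip(parent_codes, self._strides):
            idx += codes.astype(np.int64) * int(stride)
        return idx

    def describe_row(self, idx: int) -> str:
        vals = []
        rem = int(idx)
        for cats, stride in zip(self.given_cats, self._strides):
            q, rem = divmod(rem, int(stride))
            vals.append(cats[q])
        return f"P({self.target}|{','.join(self.given)}) cell {tuple(vals)!r}"


class CompiledModel:
    """All conditional tables of the tree, compiled for vectorized Gibbs updates."""

    def __init__(self, cpts: dict, schema: AttributeSchema | None = None):
        schema = schema or default_schema()
        self.schema = schema
        categories = {
            name: tuple(schema.categories(name)) for name in schema.categorical_names()
        }
        # allow tables over variables absent from the schema (generic chains)
        for table in cpts.values():
            categories.setdefault(table.target, tuple(table.categories))
        self.categories = categories
        self.tables: dict[str, _CompiledCpt] = {}
        for table in cpts.values():
            if table.target in self.tables:
                raise ValueError(f"duplicate conditional table for {table.target!r}")
            self.tables[table.target] = _CompiledCpt(table, categories)
        self.children: dict[str, list[str]] = {}
        for t in self.tables.values():
            for g in t.given:
                self.children.setdefault(g, []).append(t.target)

    def require(self, keys: Sequence[tuple[str, tuple[str, ...]]]) -> None:
        for target, given in keys:
            t = self.tables.get(target)
            if t is None or t.given != tuple(given):
                raise ConditionalError(
                    f"model is missing conditional P({target}|{','.join(given)})"
                )

    def encode(self, var: str, values) -> np.ndarray:
        cats = list(self.categories[var])
        return np.array([cats.index(v) for v in values], dtype=np.int64)

    def decode(self, var: str, codes: np.ndarray) -> list:
        cats = self.categories[var]
        return [cats[int(c)] for c in codes]

    def card(self, var: str) -> int:
        return len(self.categories[var])

    # -- full conditional ---------------------------------------------------------

    def prior_rows(self, var: str, states: dict[str, np.ndarray]) -> np.ndarray:
        """P(var | parents) rows under the current parent values."""
        t = self.tables[var]
        if not t.given:  # prior table: broadcast its single row over the entities
            n = len(next(iter(states.values())))
            return np.broadcast_to(t.array[0], (n, t.array.shape[1])).copy()
        idx = t.rows([states[p] for p in t.given])
        if not t.valid[idx].all():
            bad = int(idx[~t.valid[idx]][0])
            raise ConditionalError(f"{t.describe_row(bad)} was never estimated")
        return t.array[idx]

    def full_conditional(self, var: str, states: dict[str, np.ndarray]) -> np.ndarray:
        """Unnormalized full conditional of ``var`` given all current values:
        own conditional times the likelihood of every child's current value."""
        w = self.prior_rows(var, states).copy()
        n, k = w.shape
        for child in self.children.get(var, ()):  # var appears as a parent
            c = self.tables[child]
            if child not in states:
                continue
            y = states[child]
            lik = np.empty((n, k), dtype=float)
            pos = c.given.index(var)
            parent_codes = [states[p] for p in c.given]
            for cand in range(k):
                parent_codes[pos] = np.full(n, cand, dtype=np.int64)
                idx = c.rows(parent_codes)
                row_ok = c.valid[idx]
                vals = c.array[idx, y]
                vals[~row_ok] = 0.0
                lik[:, cand] = vals
            w *= lik
        return w


def _sample_rows(w: np.ndarray, rng: np.random.Generator, what: str) -> np.ndarray:
    """One categorical draw per row of an unnormalized weight matrix."""
    tot = w.sum(axis=1)
    if np.any(tot <= 0):
        i = int(np.argmax(tot <= 0))
        raise ConstraintError(
            f"no feasible value when sampling {what} (entity {i}: all weights zero)"
        )
    cum = np.cumsum(w, axis=1)
    u = rng.random(len(w)) * tot
    codes = (cum < u[:, None]).sum(axis=1)
    return np.minimum(codes, w.shape[1] - 1).astype(np.int64)


MaskFn = Callable[[str, dict[str, np.ndarray]], np.ndarray | None]


def gibbs_sweep(
    member_states: dict[str, np.ndarray],
    model: CompiledModel,
    sweep_order: Sequence[str],
    rng: np.random.Generator,
    mask_fn: MaskFn | None = None,
) -> dict[str, np.ndarray]:
    """One full systematic Gibbs sweep, in place.

    ``member_states`` maps variable names to integer code arrays of equal length
    (one entry per entity).  Every variable in ``sweep_order`` is resampled once
    from its full conditional; variables present in the states but not in the order
    (roles, genders, household type) stay fixed.  ``mask_fn`` may return a boolean
    feasibility mask (n, K) restricting the support of an update, which is how the
    structural rules enter the chain.
    """
    for var in sweep_order:
        w = model.full_conditional(var, member_states)
        if mask_fn is not None:
            mask = mask_fn(var, member_states)
            if mask is not None:
                w = w * mask
        member_states[var] = _sample_rows(w, rng, var)
    return member_states


# ---------------------------------------------------------------------------------
# structural masks
# ---------------------------------------------------------------------------------

def _individual_mask_fn(
    model: CompiledModel, role_codes: np.ndarray
) -> MaskFn:
    """Hard-support restrictions coupling age class, activity and SPC.

    - heads and spouses are never in the child age band (heads must reach the
      minimum head age, spouses are partners);
    - a member in the 0-15 band is a schoolchild (activity student), and a member
      whose activity is not student must be able to be an adult, so the 0-15 band
      is closed to them;
    - activity retired pins SPC to 7 (retired), activity student pins SPC to 8
      (inactive).
    """
    roles = model.categories["role"]
    activities = model.categories["main_activity"]
    spcs = model.categories["spc"]
    i_child = roles.index("child")
    i_student = activities.index("student")
    i_retired = activities.index("retired")
    i_spc7 = spcs.index(SPC_RETIRED)
    i_spc8 = spcs.index(SPC_INACTIVE)

    def mask(var: str, states: dict[str, np.ndarray]) -> np.ndarray | None:
        n = len(role_codes)
        if var == "age_class":
            m = np.ones((n, 4), dtype=bool)
            adult_only = role_codes != i_child
            if "main_activity" in states:  # absent during initialization
                adult_only = adult_only | (states["main_activity"] != i_student)
            m[adult_only, 0] = False
            return m
        if var == "main_activity":
            m = np.ones((n, len(activities)), dtype=bool)
            young = states["age_class"] == 0
            m[young] = False
            m[young, i_student] = True
            return m
        if var == "spc":
            m = np.ones((n, len(spcs)), dtype=bool)
            retired = states["main_activity"] == i_retired
            student = states["main_activity"] == i_student
            m[retired] = False
            m[retired, i_spc7] = True
            m[student] = False
            m[student, i_spc8] = True
            return m
        return None

    return mask


# ---------------------------------------------------------------------------------
# integer ages
# ---------------------------------------------------------------------------------

@dataclass
class AgeContext:
    """Feasible-age restrictions for one member: minimum from role/activity rules,
    maximum from the mother-child gap."""

    min_age: int = 0
    max_age: int = 120


def sample_age_within_class(
    age_class: str, role_context: AgeContext, rng: np.random.Generator
) -> int:
    """Uniform integer age inside the band, truncated to the member's feasible window.

    An empty window raises :class:`ConstraintError`, which callers treat as a
    signal to redraw the age class.
    """
    lo, hi = age_class_interval(age_class)
    lo = max(lo, role_context.min_age)
    hi = min(hi, role_context.max_age)
    if lo > hi:
        raise ConstraintError(
            f"age class {age_class} has no feasible age in "
            f"[{role_context.min_age}, {role_context.max_age}]"
        )
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------------
# zone generation
# ---------------------------------------------------------------------------------

def _structural_arrays(
    model: CompiledModel,
    sizes: np.ndarray,
    rng: np.random.Generator,
):
    """Household types, member roles and genders (fixed before the sweeps)."""
    type_table = model.tables["household_type"]
    types_cats = model.categories["household_type"]
    size_codes = model.encode("household_size", sizes.tolist())
    w = type_table.array[type_table.rows([size_codes])].copy()
    w[~type_table.valid[type_table.rows([size_codes])]] = 0.0
    compat = np.zeros((len(sizes), len(types_cats)), dtype=bool)
    for i, s in enumerate(sizes):
        for t in compatible_household_types(int(s)):
            compat[i, types_cats.index(t)] = True
    w = w * compat
    type_codes = _sample_rows(w, rng, "household_type")

    # roles by position
    hh_index = np.repeat(np.arange(len(sizes)), sizes)
    pos = np.concatenate([np.arange(s) for s in sizes]) if len(sizes) else np.array([], dtype=int)
    roles_cats = model.categories["role"]
    role_codes = np.empty(len(hh_index), dtype=np.int64)
    for i, (h, p) in enumerate(zip(hh_index, pos)):
        role_codes[i] = roles_cats.index(
            roles_for(types_cats[type_codes[h]], int(sizes[h]))[p]
        )

    # genders: heads and children sampled, spouse = complement of head
    genders = model.categories["gender"]
    g_table = model.tables["gender"]
    type_b = type_codes[hh_index]
    idx = g_table.rows([role_codes, type_b])
    gw = g_table.array[idx].copy()
    gw[~g_table.valid[idx]] = 0.0
    gender_codes = _sample_rows(gw, rng, "gender")
    i_head = roles_cats.index("head")
    i_spouse = roles_cats.index("spouse")
    head_gender_by_hh = np.zeros(len(sizes), dtype=np.int64)
    head_gender_by_hh[hh_index[role_codes == i_head]] = gender_codes[role_codes == i_head]
    is_spouse = role_codes == i_spouse
    gender_codes[is_spouse] = (len(genders) - 1) - head_gender_by_hh[hh_index[is_spouse]]
    return type_codes, hh_index, pos, role_codes, gender_codes


def _init_free_attributes(
    model: CompiledModel,
    ind_states: dict[str, np.ndarray],
    hh_states: dict[str, np.ndarray],
    rng: np.random.Generator,
    mask_fn: MaskFn,
) -> None:
    """Topological (ancestral) initialization: each free attribute is drawn from its
    conditional given the already-initialized ancestors, restricted by the structural
    masks.  This starts the chain inside the support of the constrained joint (a
    state drawn from per-attribute marginals can be jointly impossible, which would
    zero out a full conditional)."""

    def init(var: str, states: dict[str, np.ndarray]) -> None:
        w = model.prior_rows(var, states).copy()
        mask = mask_fn(var, states) if states is ind_states else None
        if mask is not None:
            w = w * mask
        states[var] = _sample_rows(w, rng, var)

    for var in SWEEP_ORDER_INDIVIDUAL:
        init(var, ind_states)
    for var in SWEEP_ORDER_HOUSEHOLD:
        init(var, hh_states)


def _assign_integer_ages(
    model: CompiledModel,
    ind_states: dict[str, np.ndarray],
    hh_index: np.ndarray,
    role_codes: np.ndarray,
    gender_codes: np.ndarray,
    sizes: np.ndarray,
    config: GenerationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer ages honoring head minima, the under-18 schoolchild rule and the
    mother-child gap; infeasible children have their age class (and the dependent
    chain) redrawn from the restricted conditionals."""
    roles_cats = model.categories["role"]
    activities = model.categories["main_activity"]
    genders = model.categories["gender"]
    ages_cats = model.categories["age_class"]
    i_head = roles_cats.index("head")
    i_spouse = roles_cats.index("spouse")
    i_child = roles_cats.index("child")
    i_student = activities.index("student")
    i_female = genders.index("Female")

    n = len(role_codes)
    ages = np.zeros(n, dtype=np.int64)
    cls = ind_states["age_class"]
    act = ind_states["main_activity"]

    def window(i: int, upper: int = 120) -> tuple[int, int]:
        lo, hi = age_class_interval(ages_cats[cls[i]])
        if role_codes[i] == i_head:
            lo = max(
                lo,
                config.head_min_age_multi
                if sizes[hh_index[i]] > 1
                else config.head_min_age_single,
            )
        if act[i] != i_student:
            lo = max(lo, 18)
        return lo, min(hi, upper)

    # parents first (vectorized windows, then one rng pass)
    parent = (role_codes == i_head) | (role_codes == i_spouse)
    for i in np.flatnonzero(parent):
        lo, hi = window(int(i))
        if lo > hi:
            raise ConstraintError(
                f"age class {ages_cats[cls[i]]} infeasible for role "
                f"{roles_cats[role_codes[i]]}"
            )
        ages[i] = rng.integers(lo, hi + 1)

    # mother per household: the female of the head/spouse pair, if any
    n_hh = len(sizes)
    mother_age = np.full(n_hh, -1, dtype=np.int64)
    for i in np.flatnonzero(parent):
        if gender_codes[i] == i_female:
            mother_age[hh_index[i]] = ages[i]

    for i in np.flatnonzero(role_codes == i_child):
        h = hh_index[i]
        upper = int(mother_age[h] - config.mother_child_gap) if mother_age[h] >= 0 else 120
        lo, hi = window(int(i), upper)
        if lo > hi:
            _redraw_child(model, ind_states, int(i), upper, rng)
            lo, hi = window(int(i), upper)
            if lo > hi:
                raise ConstraintError(
                    f"no feasible age for a child with mother aged {mother_age[h]}"
                )
        ages[i] = rng.integers(lo, hi + 1)
    return ages


def _redraw_child(
    model: CompiledModel,
    ind_states: dict[str, np.ndarray],
    i: int,
    upper: int,
    rng: np.random.Generator,
) -> None:
    """Redraw the age class (and dependent attributes) of one child whose integer
    window under the mother-child gap is empty."""
    ages_cats = model.categories["age_class"]
    activities = model.categories["main_activity"]
    i_student = activities.index("student")

    feasible = np.zeros(len(ages_cats), dtype=bool)
    student_only = np.zeros(len(ages_cats), dtype=bool)
    for k, label in enumerate(ages_cats):
        lo, hi = age_class_interval(label)
        hi = min(hi, upper)
        if lo <= hi:
            feasible[k] = True
            student_only[k] = max(lo, 18) > hi  # adults impossible: must be a student
    if not feasible.any():
        raise ConstraintError(f"no age class feasible below age {upper}")

    sub = {k: v[i : i + 1] for k, v in ind_states.items()}
    w = model.prior_rows("age_class", sub)[0] * feasible
    if w.sum() <= 0:
        raise ConstraintError("restricted age-class conditional has no mass")
    k = int(rng.choice(len(w), p=w / w.sum()))
    ind_states["age_class"][i] = k
    sub = {kk: v[i : i + 1] for kk, v in ind_states.items()}
    aw = model.prior_rows("main_activity", sub)[0].copy()
    if k == 0 or student_only[k]:
        keep = np.zeros_like(aw, dtype=bool)
        keep[i_student] = True
        aw = aw * keep
    if aw.sum() <= 0:
        raise ConstraintError("restricted activity conditional has no mass")
    ind_states["main_activity"][i] = int(rng.choice(len(aw), p=aw / aw.sum()))
    mask_one = _individual_mask_fn(model, ind_states["role"][i : i + 1])
    for var in ("spc", "education"):  # ancestral redraw down the chain
        sub = {kk: v[i : i + 1] for kk, v in ind_states.items()}
        w = model.prior_rows(var, sub)[0].copy()
        mask = mask_one(var, sub)
        if mask is not None:
            w = w * mask[0]
        if w.sum() <= 0:
            raise ConstraintError(f"restricted {var} conditional has no mass")
        ind_states[var][i] = int(rng.choice(len(w), p=w / w.sum()))


def _generate_households(
    zone_id: str,
    sizes: np.ndarray,
    model: CompiledModel,
    config: GenerationConfig,
    rng: np.random.Generator,
    ancestral: bool = False,
) -> Population:
    """Generate all households of one zone given their sizes.

    ``ancestral=True`` draws each attribute once in topological order (exact forward
    sampling from the tree); otherwise attributes are initialized from their
    marginals and refined with ``config.burn_in`` Gibbs sweeps.
    """
    model.require(REQUIRED_CPTS)
    sizes = np.asarray(sizes, dtype=np.int64)
    n_hh = len(sizes)
    if n_hh == 0:
        return Population(
            pd.DataFrame(
                columns=[
                    "household_id", "zone_id", "household_size", "household_type",
                    "income_class", "car_ownership", "income",
                ]
            ),
            pd.DataFrame(
                columns=[
                    "individual_id", "household_id", "zone_id", "role", "age",
                    "age_class", "gender", "spc", "education", "main_activity",
                    "income", "overweight",
                ]
            ),
        )

    type_codes, hh_index, pos, role_codes, gender_codes = _structural_arrays(
        model, sizes, rng
    )
    ind_states: dict[str, np.ndarray] = {
        "household_type": type_codes[hh_index],
        "role": role_codes,
        "gender": gender_codes,
    }
    hh_states: dict[str, np.ndarray] = {"household_type": type_codes}
    mask_fn = _individual_mask_fn(model, role_codes)
    _init_free_attributes(model, ind_states, hh_states, rng, mask_fn)

    if not ancestral:
        for _ in range(config.burn_in):
            gibbs_sweep(ind_states, model, SWEEP_ORDER_INDIVIDUAL, rng, mask_fn)
            gibbs_sweep(hh_states, model, SWEEP_ORDER_HOUSEHOLD, rng)

    ages = _assign_integer_ages(
        model, ind_states, hh_index, role_codes, gender_codes, sizes, config, rng
    )

    hh_ids = [f"{zone_id}-H{i:06d}" for i in range(n_hh)]
    households = pd.DataFrame(
        {
            "household_id": hh_ids,
            "zone_id": zone_id,
            "household_size": sizes,
            "household_type": model.decode("household_type", type_codes),
            "income_class": model.decode("income_class", hh_states["income_class"]),
            "car_ownership": model.decode("car_ownership", hh_states["car_ownership"]),
            "income": np.nan,
        }
    )
    individuals = pd.DataFrame(
        {
            "individual_id": [
                f"{hh_ids[h]}-P{p}" for h, p in zip(hh_index, pos)
            ],
            "household_id": [hh_ids[h] for h in hh_index],
            "zone_id": zone_id,
            "role": model.decode("role", role_codes),
            "age": ages,
            "age_class": model.decode("age_class", ind_states["age_class"]),
            "gender": model.decode("gender", gender_codes),
            "spc": model.decode("spc", ind_states["spc"]),
            "education": model.decode("education", ind_states["education"]),
            "main_activity": model.decode("main_activity", ind_states["main_activity"]),
            "income": np.nan,
            "overweight": pd.array([pd.NA] * len(hh_index), dtype="Int64"),
        }
    )
    return Population(households, individuals)


def generate_zone_population(
    zone_id: str,
    cpts: dict | CompiledModel,
    size_dist: Sequence[float],
    config: GenerationConfig | None = None,
    rng: np.random.Generator | None = None,
    population: int | None = None,
) -> Population:
    """Generate the full synthetic population of one zone.

    The zone's individual count is integerized into household counts by size, and
    every household is co-generated by burn-in Gibbs sweeps over the conditional
    tree.  Total generated individuals equal ``population`` (within one where exact
    integerization is infeasible).
    """
    config = config or GenerationConfig()
    if population is None:
        raise ValueError("zone population count is required")
    model = cpts if isinstance(cpts, CompiledModel) else CompiledModel(cpts)
    rng = rng if rng is not None else zone_rng(config.master_seed, zone_id)
    counts = integerize_household_counts(population, size_dist)
    sizes = np.repeat(np.arange(1, 7), counts)
    return _generate_households(zone_id, sizes, model, config, rng)


def generate_household(
    zone_id: str,
    size: int,
    cpts: dict | CompiledModel,
    config: GenerationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Household:
    """Co-generate a single structurally valid household of the given size."""
    if not 1 <= size <= 6:
        raise ValueError(f"household size {size} outside 1..6")
    config = config or GenerationConfig()
    model = cpts if isinstance(cpts, CompiledModel) else CompiledModel(cpts)
    rng = rng if rng is not None else zone_rng(config.master_seed, zone_id)
    pop = _generate_households(zone_id, np.array([size]), model, config, rng)
    hh_row = pop.households.iloc[0]
    members = [
        Individual(
            individual_id=r.individual_id,
            household_id=r.household_id,
            role=r.role,
            age=int(r.age),
            age_class=r.age_class,
            gender=r.gender,
            spc=int(r.spc),
            education=r.education,
            main_activity=r.main_activity,
        )
        for r in pop.individuals.itertuples(index=False)
    ]
    return Household(
        household_id=hh_row.household_id,
        zone_id=zone_id,
        size=int(hh_row.household_size),
        household_type=hh_row.household_type,
        income_class=hh_row.income_class,
        car_ownership=int(hh_row.car_ownership),
        members=members,
    )


# ---------------------------------------------------------------------------------
# invariant checking
# ---------------------------------------------------------------------------------

def validate_population(
    pop: Population, config: GenerationConfig | None = None
) -> list[str]:
    """Exhaustive structural audit; returns a list of violation messages (empty when
    the population is valid)."""
    config = config or GenerationConfig()
    problems: list[str] = []
    hh = pop.households
    ind = pop.individuals.merge(
        hh[["household_id", "household_size", "household_type"]],
        on="household_id",
        how="left",
    )
    ind["pos"] = ind.groupby("household_id", sort=False).cumcount()

    def report(mask: pd.Series, message: str, id_col: str = "individual_id") -> None:
        for ident in ind.loc[mask, id_col] if id_col in ind else hh.loc[mask, id_col]:
            problems.append(f"{ident}: {message}")

    counts = ind.groupby("household_id", sort=False).size()
    mismatch = hh.set_index("household_id")["household_size"]
    bad_counts = counts[counts != mismatch.loc[counts.index]]
    problems.extend(f"{h}: member count != declared size" for h in bad_counts.index)

    bad_type = (hh["household_size"] == 1) != (hh["household_type"] == "Single")
    problems.extend(
        f"{h}: size inconsistent with type Single"
        for h in hh.loc[bad_type, "household_id"]
    )

    has_spouse = ind["household_type"].isin(["couple", "family"])
    expected_role = np.where(
        ind["pos"] == 0,
        "head",
        np.where((ind["pos"] == 1) & has_spouse, "spouse", "child"),
    )
    report(ind["role"].to_numpy() != expected_role, "role does not match position")

    heads = ind[ind["role"] == "head"]
    min_age = np.where(
        heads["household_size"] > 1,
        config.head_min_age_multi,
        config.head_min_age_single,
    )
    for ident in heads.loc[heads["age"].to_numpy() < min_age, "individual_id"]:
        problems.append(f"{ident}: head below minimum age")

    head_gender = heads.set_index("household_id")["gender"]
    spouses = ind[ind["role"] == "spouse"]
    same = spouses["gender"].to_numpy() == head_gender.loc[
        spouses["household_id"]
    ].to_numpy()
    for ident in spouses.loc[same, "individual_id"]:
        problems.append(f"{ident}: spouse gender equals head gender")

    parents = ind[ind["role"].isin(["head", "spouse"])]
    mothers = parents[parents["gender"] == "Female"].set_index("household_id")["age"]
    kids = ind[ind["role"] == "child"]
    eldest = kids.groupby("household_id")["age"].max()
    both = mothers.index.intersection(eldest.index)
    gap_bad = mothers.loc[both] - eldest.loc[both] < config.mother_child_gap
    problems.extend(
        f"{h}: mother-child age gap below {config.mother_child_gap}"
        for h in both[gap_bad.to_numpy()]
    )

    under18 = ind["age"] < 18
    report(under18 & (ind["main_activity"] != "student"), "under-18 not a schoolchild")
    report(under18 & (ind["spc"] != SPC_INACTIVE), "under-18 with active SPC")
    report(
        (ind["age"] >= 65) & (ind["main_activity"] == "retired") & (ind["spc"] != SPC_RETIRED),
        "retired 65+ without retired SPC",
    )
    return problems
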