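"""Synthetic NEAT-design data for testlet-equating simulations.

Each simulated test form has 60 items: 20 locally independent non-anchor
items, 20 non-anchor testlet items (4 testlets of 5 or 2 of 10), 10 anchor
testlet items (2 testlets of 5 or 1 of 10) and 10 independent anchor items.
Anchor items and anchor testlets are shared verbatim between the base and
new forms (internal anchor).

True parameters are drawn by rejection sampling (never clipping):

* discrimination ``a = exp(z)``, ``z ~ N(0,1)``, accepted when ``a`` lies in
  (0, 2.5) for non-anchor items and (1, 2) for anchor items;
* difficulty / category boundaries ``~ N(0,1)`` accepted in (-3, 3),
  boundaries sorted into strictly increasing order;
* testlet-effect variances ``sigma2 ~ U(0.1, 0.5) / U(0.6, 1.0) / U(1.1, 2.0)``
  for low / moderate / high local item dependence.

Base-group abilities are N(0,1); the new group is N(shift, 1) with a
configurable mean shift (default +0.5).  Response generation always uses the
testlet model (the random effects exist in every generating condition);
fitting the non-testlet family to these data is the deliberate
misspecification under study.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .models import (
    MISSING,
    DichotomousItemParams,
    ItemParams,
    PolytomousItemParams,
    TestletSpec,
    dich_prob_array,
    grm_cumulative_array,
)

#: Uniform ranges for the testlet-effect variance by level of local dependence.
VARIANCE_RANGES: dict[str, tuple[float, float]] = {
    "low": (0.1, 0.5),
    "moderate": (0.6, 1.0),
    "high": (1.1, 2.0),
}

#: Conventional numeric labels for the three effect levels (upper range ends).
EFFECT_LABELS: dict[str, float] = {"low": 0.5, "moderate": 1.0, "high": 2.0}

#: Truncation interval of the lognormal discrimination by item role.
A_BOUNDS: dict[str, tuple[float, float]] = {"non_anchor": (0.0, 2.5), "anchor": (1.0, 2.0)}
B_BOUNDS: tuple[float, float] = (-3.0, 3.0)

_FIXTURE_SHA256 = {
    "dichotomous": "c417e8e4de50cf015c008c2c1503289e6bdf6a66f8c2cb5166bb0e481905e852",
    "polytomous": "f1cf0087225664798c885e3f5c07b67165d0d532d7a19709cd7cc71ca059afc9",
}


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the factorial design (plus run bookkeeping)."""

    data_family: str = "dichotomous"  # 'dichotomous' | 'polytomous'
    testlet_effect: str = "low"  # 'low' | 'moderate' | 'high'
    testlet_length: int = 5  # 5 | 10
    sample_size: int = 1000  # examinees per group
    n_replications: int = 500
    seed: int = 0
    new_form_mean_shift: float = 0.5
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.data_family not in ("dichotomous", "polytomous"):
            raise ValueError(f"unknown data family {self.data_family!r}")
        if self.testlet_effect not in VARIANCE_RANGES:
            raise ValueError(f"unknown testlet-effect level {self.testlet_effect!r}")
        if self.testlet_length not in (5, 10):
            raise ValueError("testlet_length must be 5 or 10 (each form has 30 testlet items)")
        if self.sample_size < 1 or self.n_replications < 1:
            raise ValueError("sample_size and n_replications must be positive")


@dataclass(frozen=True)
class FormPair:
    """A base/new form pair sharing an internal anchor block."""

    base_items: tuple[ItemParams, ...]
    new_items: tuple[ItemParams, ...]
    anchor_ids: frozenset[str]
    base_testlets: tuple[TestletSpec, ...]
    new_testlets: tuple[TestletSpec, ...]

    def testlets_for(self, side: str) -> tuple[TestletSpec, ...]:
        return self.base_testlets if side == "base" else self.new_testlets

    def items_for(self, side: str) -> tuple[ItemParams, ...]:
        return self.base_items if side == "base" else self.new_items

    def all_items(self) -> dict[str, ItemParams]:
        """Distinct items keyed by id (anchors appear once)."""
        out: dict[str, ItemParams] = {}
        for it in (*self.base_items, *self.new_items):
            prev = out.setdefault(it.item_id, it)
            if prev is not it and prev != it:
                raise ValueError(f"item {it.item_id!r} has conflicting parameters across forms")
        return out

    def all_testlets(self) -> dict[str, TestletSpec]:
        out: dict[str, TestletSpec] = {}
        for spec in (*self.base_testlets, *self.new_testlets):
            prev = out.setdefault(spec.testlet_id, spec)
            if prev is not spec and prev != spec:
                raise ValueError(f"testlet {spec.testlet_id!r} differs across forms")
        return out

    def validate(self, testlet_length: int | None = None) -> None:
        for side in ("base", "new"):
            items = self.items_for(side)
            if len(items) != 60:
                raise ValueError(f"{side} form must have 60 items, got {len(items)}")
            ids = [it.item_id for it in items]
            if len(set(ids)) != 60:
                raise ValueError(f"{side} form has duplicate item ids")
            anchors = [i for i in ids if i in self.anchor_ids]
            if len(anchors) != 20:
                raise ValueError(f"{side} form must contain 20 anchor items, got {len(anchors)}")
        self.all_items()  # raises on anchor parameter mismatch
        if testlet_length is not None:
            for spec in self.all_testlets().values():
                if len(spec.item_ids) != testlet_length:
                    raise ValueError(
                        f"testlet {spec.testlet_id!r} has {len(spec.item_ids)} items, "
                        f"expected {testlet_length}"
                    )


@dataclass(frozen=True)
class PersonSample:
    """Latent abilities and per-testlet random effects for one examinee group."""

    group: str  # 'base' | 'new'
    thetas: np.ndarray  # (n,)
    gammas: dict[str, np.ndarray] = field(default_factory=dict)  # testlet_id -> (n,)

    @property
    def n(self) -> int:
        return len(self.thetas)


@dataclass(frozen=True)
class ResponseMatrix:
    """Stacked two-group response matrix with structural missingness.

    ``codes`` is (persons x distinct items) of integer response codes with
    ``MISSING`` marking items a person's group did not take.
    """

    codes: np.ndarray
    item_ids: tuple[str, ...]
    groups: np.ndarray  # (n,) array of 'base' / 'new'

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.groups), len(self.item_ids)):
            raise ValueError("codes shape inconsistent with item_ids / groups")

    def column(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=list(self.item_ids))
        df.insert(0, "group", self.groups)
        return df


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def _rejection(draw, accept, rng, size: int) -> np.ndarray:
    """Draw until ``size`` values satisfy ``accept`` (batched rejection)."""
    out: list[np.ndarray] = []
    need = size
    while need > 0:
        cand = draw(rng, max(need * 2, 16))
        good = cand[accept(cand)]
        out.append(good[:need])
        need -= len(good[:need])
    return np.concatenate(out)


def sample_discriminations(role: str, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    lo, hi = A_BOUNDS[role]
    return _rejection(
        lambda r, m: np.exp(r.standard_normal(m)),
        lambda a: (a > lo) & (a < hi),
        rng,
        size,
    )


def _sample_truncated_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    lo, hi = B_BOUNDS
    return _rejection(
        lambda r, m: r.standard_normal(m),
        lambda b: (b > lo) & (b < hi),
        rng,
        size,
    )


def sample_dichotomous_params(role: str, rng: np.random.Generator) -> tuple[float, float]:
    """One (a, b) draw: truncated lognormal discrimination, truncated normal difficulty."""
    if role not in A_BOUNDS:
        raise ValueError(f"role must be one of {sorted(A_BOUNDS)}, got {role!r}")
    a = float(sample_discriminations(role, rng, 1)[0])
    b = float(_sample_truncated_normal(rng, 1)[0])
    return a, b


def sample_polytomous_params(
    role: str, rng: np.random.Generator, n_categories: int = 5
) -> tuple[float, tuple[float, ...]]:
    """One (a, boundaries) draw; boundaries are sorted truncated-normal order statistics."""
    if role not in A_BOUNDS:
        raise ValueError(f"role must be one of {sorted(A_BOUNDS)}, got {role!r}")
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    a = float(sample_discriminations(role, rng, 1)[0])
    while True:
        bs = np.sort(_sample_truncated_normal(rng, n_categories - 1))
        if np.all(np.diff(bs) > 0) or len(bs) == 1:
            break
    return a, tuple(float(x) for x in bs)


def draw_testlet_variances(level: str, n_testlets: int, rng: np.random.Generator) -> np.ndarray:
    """Per-testlet random-effect variances from the level's uniform range."""
    if level not in VARIANCE_RANGES:
        raise ValueError(f"unknown testlet-effect level {level!r}")
    lo, hi = VARIANCE_RANGES[level]
    return rng.uniform(lo, hi, size=n_testlets)


# ---------------------------------------------------------------------------
# Form construction
# ---------------------------------------------------------------------------

def _form_layout(testlet_length: int) -> tuple[int, int]:
    """(non-anchor testlet count, anchor testlet count) for the given length."""
    if testlet_length == 5:
        return 4, 2
    if testlet_length == 10:
        return 2, 1
    raise ValueError("testlet_length must be 5 or 10")


def _make_item(
    family: str, item_id: str, role: str, testlet_id: str | None,
    rng: np.random.Generator, n_categories: int,
) -> ItemParams:
    if family == "dichotomous":
        a, b = sample_dichotomous_params(role, rng)
        return DichotomousItemParams(item_id, a, b, testlet_id)
    a, bs = sample_polytomous_params(role, rng, n_categories)
    return PolytomousItemParams(item_id, a, bs, testlet_id)


def build_form_pair(condition: SimulationCondition, rng: np.random.Generator) -> FormPair:
    """Sample a full NEAT form pair for one condition.

    Anchor items (and anchor-testlet variances) are drawn once and shared by
    both forms; everything else is drawn independently per form.
    """
    n_nonanchor_t, n_anchor_t = _form_layout(condition.testlet_length)
    L = condition.testlet_length
    fam, K = condition.data_family, condition.n_categories

    def build_side(side: str) -> tuple[list[ItemParams], list[TestletSpec]]:
        items: list[ItemParams] = []
        specs: list[TestletSpec] = []
        prefix = side[0]
        # 20 independent non-anchor items (ids 1-20)
        for j in range(1, 21):
            items.append(_make_item(fam, f"{prefix}{j:02d}", "non_anchor", None, rng, K))
        # non-anchor testlets (items 21-40)
        sig = draw_testlet_variances(condition.testlet_effect, n_nonanchor_t, rng)
        j = 21
        for t in range(n_nonanchor_t):
            tid = f"{side}_t{t + 1}"
            member_ids = []
            for _ in range(L):
                it = _make_item(fam, f"{prefix}{j:02d}", "non_anchor", tid, rng, K)
                items.append(it)
                member_ids.append(it.item_id)
                j += 1
            specs.append(TestletSpec(tid, tuple(member_ids), float(sig[t])))
        return items, specs

    base_items, base_specs = build_side("base")
    new_items, new_specs = build_side("new")

    # shared anchor block: testlet items 41-50 then independent items 51-60
    anchor_items: list[ItemParams] = []
    anchor_specs: list[TestletSpec] = []
    sig = draw_testlet_variances(condition.testlet_effect, n_anchor_t, rng)
    j = 41
    for t in range(n_anchor_t):
        tid = f"anchor_t{t + 1}"
        member_ids = []
        for _ in range(L):
            it = _make_item(fam, f"a{j:02d}", "anchor", tid, rng, K)
            anchor_items.append(it)
            member_ids.append(it.item_id)
            j += 1
        anchor_specs.append(TestletSpec(tid, tuple(member_ids), float(sig[t])))
    for j in range(51, 61):
        anchor_items.append(_make_item(fam, f"a{j:02d}", "anchor", None, rng, K))

    pair = FormPair(
        base_items=tuple(base_items + anchor_items),
        new_items=tuple(new_items + anchor_items),
        anchor_ids=frozenset(it.item_id for it in anchor_items),
        base_testlets=tuple(base_specs + anchor_specs),
        new_testlets=tuple(new_specs + anchor_specs),
    )
    pair.validate(testlet_length=L)
    return pair


# ---------------------------------------------------------------------------
# Printed form pairs (packaged fixtures)
# ---------------------------------------------------------------------------

def load_printed_table(study: str) -> pd.DataFrame:
    """The published item-parameter table for one study, verbatim.

    Columns: form ('reference'/'new'), item (1-60), testlet (float, NaN for
    independent items), anchor (0/1), and a, b (dichotomous) or a, b1..b4
    (polytomous).
    """
    if study not in _FIXTURE_SHA256:
        raise ValueError(f"study must be 'dichotomous' or 'polytomous', got {study!r}")
    ref = resources.files("trtequate.data") / f"{study}_forms.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[study]:
        raise RuntimeError(
            f"packaged fixture {study}_forms.tsv is corrupted (sha256 {digest})"
        )
    import io as _io

    return pd.read_csv(_io.BytesIO(raw), sep="\t")


def load_printed_forms(study: str, link_anchors: bool = True) -> FormPair:
    """Build a :class:`FormPair` from the published tables.

    The published reference-form and new-form anchor blocks are not numerically
    identical; a NEAT concurrent calibration requires a truly shared anchor.
    With ``link_anchors=True`` (default) the reference form's printed anchor
    parameters and testlet layout are used for both forms.  With
    ``link_anchors=False`` both forms are returned verbatim with
    form-specific anchor item ids (no shared columns).

    Testlet variances are not published; every spec gets ``sigma2=0`` and
    callers assign variances via :func:`assign_testlet_variances`.
    """
    df = load_printed_table(study)
    poly = study == "polytomous"

    def row_item(row, item_id: str, tid: str | None) -> ItemParams:
        if poly:
            bs = np.array([float(row[f"b{k}"]) for k in range(1, 5)])
            # resolve ties introduced by the table's two-decimal rounding
            for k in range(1, 4):
                if bs[k] <= bs[k - 1]:
                    bs[k] = bs[k - 1] + 1e-6
            return PolytomousItemParams(item_id, float(row["a"]), tuple(bs), tid)
        return DichotomousItemParams(item_id, float(row["a"]), float(row["b"]), tid)

    def build(form: str, prefix: str, anchor_prefix: str) -> tuple[list[ItemParams], list[TestletSpec]]:
        sub = df[df["form"] == form].sort_values("item")
        items: list[ItemParams] = []
        members: dict[str, list[str]] = {}
        for _, row in sub.iterrows():
            num = int(row["item"])
            anchor = bool(row["anchor"])
            item_id = f"{anchor_prefix}{num:02d}" if anchor else f"{prefix}{num:02d}"
            tid = None
            if not pd.isna(row["testlet"]):
                tid = f"{anchor_prefix if anchor else prefix}_t{int(row['testlet'])}"
                members.setdefault(tid, []).append(item_id)
            items.append(row_item(row, item_id, tid))
        specs = [TestletSpec(tid, tuple(ids), 0.0) for tid, ids in members.items()]
        return items, specs

    if link_anchors:
        ref_items, ref_specs = build("reference", "b", "anc")
        new_items, new_specs = build("new", "n", "anc")
        # use the reference form's printed anchor block for both forms
        ref_anchor = [it for it in ref_items if it.item_id.startswith("anc")]
        anchor_ids = frozenset(it.item_id for it in ref_anchor)
        anchor_tids = {it.testlet_id for it in ref_anchor if it.testlet_id is not None}
        anchor_specs = [s for s in ref_specs if s.testlet_id in anchor_tids]
        new_items = [it for it in new_items if not it.item_id.startswith("anc")] + ref_anchor
        new_specs = [s for s in new_specs if s.testlet_id not in anchor_tids] + anchor_specs
        return FormPair(
            base_items=tuple(ref_items),
            new_items=tuple(new_items),
            anchor_ids=anchor_ids,
            base_testlets=tuple(ref_specs),
            new_testlets=tuple(new_specs),
        )
    ref_items, ref_specs = build("reference", "b", "ba")
    new_items, new_specs = build("new", "n", "na")
    return FormPair(
        base_items=tuple(ref_items),
        new_items=tuple(new_items),
        anchor_ids=frozenset(),
        base_testlets=tuple(ref_specs),
        new_testlets=tuple(new_specs),
    )


def printed_form_pair(study: str, testlet_length: int = 5) -> FormPair:
    """A NEAT form pair built from the published parameter values.

    Item parameters come verbatim from the published tables (reference form
    as the base form; the reference form's anchor block shared by both
    forms), while testlet membership follows the requested testlet length:
    items 21-40 form the non-anchor testlets and items 41-50 the anchor
    testlets, in consecutive runs of ``testlet_length``.  Testlet variances
    are zero until assigned via :func:`assign_testlet_variances`.
    """
    n_nonanchor_t, n_anchor_t = _form_layout(testlet_length)
    df = load_printed_table(study)
    poly = study == "polytomous"

    def row_item(row, item_id: str, tid: str | None) -> ItemParams:
        if poly:
            bs = np.array([float(row[f"b{k}"]) for k in range(1, 5)])
            # two-decimal rounding in the published table produces occasional
            # tied boundaries; nudge them apart so the graded model is valid
            for k in range(1, 4):
                if bs[k] <= bs[k - 1]:
                    bs[k] = bs[k - 1] + 1e-6
            return PolytomousItemParams(item_id, float(row["a"]), tuple(bs), tid)
        return DichotomousItemParams(item_id, float(row["a"]), float(row["b"]), tid)

    def tid_for(num: int, side: str) -> str | None:
        if 21 <= num <= 40:
            return f"{side}_t{(num - 21) // testlet_length + 1}"
        if 41 <= num <= 50:
            return f"anchor_t{(num - 41) // testlet_length + 1}"
        return None

    ref = df[df["form"] == "reference"].sort_values("item")
    new = df[df["form"] == "new"].sort_values("item")

    def build(sub, side: str, prefix: str) -> tuple[list[ItemParams], dict[str, list[str]]]:
        items, members = [], {}
        for _, row in sub.iterrows():
            num = int(row["item"])
            if num > 40 and side == "new":
                continue  # anchors come from the reference rows
            item_id = f"a{num:02d}" if num > 40 else f"{prefix}{num:02d}"
            tid = tid_for(num, side if num <= 40 else "anchor")
            if tid is not None:
                members.setdefault(tid, []).append(item_id)
            items.append(row_item(row, item_id, tid))
        return items, members

    base_items, base_members = build(ref, "base", "b")
    new_items, new_members = build(new, "new", "n")
    anchor_items = [it for it in base_items if it.item_id.startswith("a")]
    new_items = new_items + anchor_items
    anchor_members = {t: ids for t, ids in base_members.items() if t.startswith("anchor")}
    new_members.update(anchor_members)

    def specs(members: dict[str, list[str]]) -> tuple[TestletSpec, ...]:
        return tuple(TestletSpec(t, tuple(ids), 0.0) for t, ids in sorted(members.items()))

    pair = FormPair(
        base_items=tuple(base_items),
        new_items=tuple(new_items),
        anchor_ids=frozenset(it.item_id for it in anchor_items),
        base_testlets=specs(base_members),
        new_testlets=specs(new_members),
    )
    pair.validate(testlet_length=testlet_length)
    return pair


def assign_testlet_variances(pair: FormPair, level: str, rng: np.random.Generator) -> FormPair:
    """Return a copy of ``pair`` with fresh sigma2 draws at the given effect level."""
    tids = sorted(pair.all_testlets())
    sig = dict(zip(tids, draw_testlet_variances(level, len(tids), rng)))

    def upd(specs: tuple[TestletSpec, ...]) -> tuple[TestletSpec, ...]:
        return tuple(replace(s, sigma2=float(sig[s.testlet_id])) for s in specs)

    return replace(pair, base_testlets=upd(pair.base_testlets), new_testlets=upd(pair.new_testlets))


# ---------------------------------------------------------------------------
# Persons and responses
# ---------------------------------------------------------------------------

def sample_persons(
    n: int,
    group: str,
    testlets: tuple[TestletSpec, ...] | list[TestletSpec],
    rng: np.random.Generator,
    new_form_mean_shift: float = 0.5,
) -> PersonSample:
    """Draw abilities and per-testlet random effects for one examinee group."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if group not in ("base", "new"):
        raise ValueError("group must be 'base' or 'new'")
    mean = new_form_mean_shift if group == "new" else 0.0
    thetas = rng.normal(mean, 1.0, size=n)
    gammas = {
        spec.testlet_id: rng.normal(0.0, np.sqrt(spec.sigma2), size=n) for spec in testlets
    }
    return PersonSample(group=group, thetas=thetas, gammas=gammas)


def generate_responses(
    items: tuple[ItemParams, ...] | list[ItemParams],
    persons: PersonSample,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the (n x items) response block for one form side.

    Generation always uses the testlet model: the random effect enters the
    logit for every testlet item.  Dichotomous items code 1 when the model
    probability exceeds a U(0,1) draw; graded items locate the draw within
    the cumulative category partition.
    """
    n = persons.n
    codes = np.empty((n, len(items)), dtype=np.int16)
    for j, item in enumerate(items):
        if item.testlet_id is not None:
            if item.testlet_id not in persons.gammas:
                raise KeyError(
                    f"person sample lacks random effects for testlet {item.testlet_id!r}"
                )
            trait = persons.thetas - persons.gammas[item.testlet_id]
        else:
            trait = persons.thetas
        u = rng.uniform(size=n)
        if isinstance(item, DichotomousItemParams):
            codes[:, j] = (dich_prob_array(item.a, item.b, trait) > u).astype(np.int16)
        else:
            star = grm_cumulative_array(item.a, np.asarray(item.boundaries), trait)
            codes[:, j] = (u <= star).sum(axis=0).astype(np.int16)
    return codes


def assemble_concurrent_matrix(
    base_block: np.ndarray, new_block: np.ndarray, pair: FormPair
) -> ResponseMatrix:
    """Stack the two form-side blocks into one concurrent-calibration matrix.

    Anchor columns are merged; form-specific columns are padded with the
    missing marker for the other group.
    """
    base_ids = [it.item_id for it in pair.base_items]
    new_ids = [it.item_id for it in pair.new_items]
    if base_block.shape[1] != len(base_ids) or new_block.shape[1] != len(new_ids):
        raise ValueError("response blocks do not match the form layouts")
    all_ids = list(base_ids) + [i for i in new_ids if i not in set(base_ids)]
    col = {i: k for k, i in enumerate(all_ids)}
    n_b, n_n = len(base_block), len(new_block)
    codes = np.full((n_b + n_n, len(all_ids)), MISSING, dtype=np.int16)
    for j, i in enumerate(base_ids):
        codes[:n_b, col[i]] = base_block[:, j]
    for j, i in enumerate(new_ids):
        codes[n_b:, col[i]] = new_block[:, j]
    groups = np.array(["base"] * n_b + ["new"] * n_n)
    return ResponseMatrix(codes=codes, item_ids=tuple(all_ids), groups=groups)


def replication_rng(master_seed: int, condition_index: int, replication: int) -> np.random.Generator:
    """The documented seed-splitting rule: one independent stream per replication."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(condition_index), int(replication)])
    )
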