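"""Linear birth-death model of gene-family copy-number evolution on a tree.

Each gene copy independently duplicates or is lost at rate lambda (events per
gene per million years); zero copies is absorbing.  The per-branch transition
probability has the classical closed form

    P(c | s, t) = sum_{j=0..min(s,c)} C(s,j) C(s+c-j-1, s-1)
                  a^(s+c-2j) (1-2a)^j,      a = lambda*t / (1 + lambda*t)

for a parent with s >= 1 copies; the zero state is absorbing.  Family
likelihoods are computed by pruning (post-order dynamic programming) over
copy-number states 0..n_max with the root marginalized against a uniform
prior on {1, ..., root_max}; ancestral states by max-product (Viterbi)
dynamic programming with ties broken toward the smaller count.

Branch-shift significance is an exact two-sided tail test: the probability,
under the fitted model, of any parent->child transition as likely or less
likely than the one observed.  Family-wide conservation is a Monte Carlo
test comparing the observed family likelihood with likelihoods of families
simulated under the fitted model.

Time units: tree branch lengths are in ky; lambda is per My, so branch
lengths are divided by 1000 inside every rate computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .tree import KY_PER_MY, UltrametricTree, parse_newick

__all__ = [
    "FamilyProfile",
    "BDPModel",
    "bdp_transition_prob",
    "transition_matrix",
    "family_loglik",
    "fit_lambda",
    "reconstruct_ancestral",
    "branch_shift_pvalue",
    "family_conservation_pvalue",
    "simulate_profiles",
    "subsample_robustness",
    "CopyNumberEvolutionModel",
    "CopyNumberEvolutionResults",
]

# Bonferroni divisors from the study design: ten branches, nine families.
BRANCH_TEST_DIVISOR = 10
FAMILY_TEST_DIVISOR = 9


@dataclass(frozen=True)
class FamilyProfile:
    """One gene family's copy number per species (tree tips).

    Counts are the per-species medians of per-individual estimates, rounded
    half up; families lost or pseudogenized in a species carry a zero.
    """

    name: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for sp, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {sp!r} in family {self.name!r}")
        if self.counts and max(self.counts.values()) == 0:
            raise ValueError(f"family {self.name!r} has no species with a positive count")

    @property
    def max_count(self) -> int:
        return max(self.counts.values())

    def check_tree(self, tree: UltrametricTree) -> None:
        missing = sorted(set(tree.tip_labels) - set(self.counts))
        if missing:
            raise ValueError(
                f"family {self.name!r} is missing counts for species: {missing}"
            )


@dataclass
class BDPModel:
    """Birth-death rate and state-space truncation.

    lambda_ is in events per gene per My.  n_max truncates the copy-number
    state space (tail mass below ~1e-10 at the study's rates); root_max sets
    the support of the uniform root prior {1, ..., root_max}.
    """

    lambda_: float
    n_max: int
    root_max: int

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.root_max < 1 or self.n_max < self.root_max:
            raise ValueError("need 1 <= root_max <= n_max")


def default_n_max(max_observed: int) -> int:
    return max(100, 3 * max_observed)


def default_root_max(max_observed: int) -> int:
    return max(1, 2 * max_observed)


# ---------------------------------------------------------------------------
# transition kernel
# ---------------------------------------------------------------------------

def bdp_transition_prob(s: int, c: int, t: float, lam: float) -> float:
    """P(child count c | parent count s) over a branch of t My at rate lam.

    Direct evaluation of the closed-form sum; exact binomial coefficients keep
    the alternating (1-2a)^j terms accurate.
    """
    if s < 0 or c < 0 or t < 0 or lam < 0:
        raise ValueError("s, c, t and lambda must all be non-negative")
    if s == 0:
        return 1.0 if c == 0 else 0.0
    lt = lam * t
    if lt == 0.0:
        return 1.0 if c == s else 0.0
    a = lt / (1.0 + lt)
    one_minus_2a = 1.0 - 2.0 * a
    total = 0.0
    for j in range(min(s, c) + 1):
        coef = math.comb(s, j) * math.comb(s + c - j - 1, s - 1)
        total += coef * a ** (s + c - 2 * j) * one_minus_2a**j
    # guard against negative round-off on extreme tails
    return max(total, 0.0)


def transition_matrix(t: float, lam: float, n_max: int) -> np.ndarray:
    """Transition matrix P[s, c] for s, c in 0..n_max over t My at rate lam.

    Row s is the s-fold convolution of the single-copy offspring distribution
    p(0)=a, p(k)=(1-a)^2 a^(k-1); truncation at n_max is exact for the
    retained entries (higher states never feed back into lower ones within a
    single branch).
    """
    lt = lam * t
    if lt == 0.0:
        return np.eye(n_max + 1)
    a = lt / (1.0 + lt)
    p1 = np.empty(n_max + 1)
    p1[0] = a
    if n_max >= 1:
        p1[1:] = (1.0 - a) ** 2 * a ** np.arange(n_max)
    P = np.zeros((n_max + 1, n_max + 1))
    P[0, 0] = 1.0
    row = np.zeros(n_max + 1)
    row[0] = 1.0
    for s in range(1, n_max + 1):
        row = np.convolve(row, p1)[: n_max + 1]
        P[s] = row
    return P


class _MatrixCache:
    """Per-lambda cache of branch transition matrices."""

    def __init__(self, lam: float, n_max: int):
        self.lam = lam
        self.n_max = n_max
        self._store: dict[float, np.ndarray] = {}

    def get(self, t_ky: float) -> np.ndarray:
        key = float(t_ky)
        if key not in self._store:
            self._store[key] = transition_matrix(key / KY_PER_MY, self.lam, self.n_max)
        return self._store[key]


# ---------------------------------------------------------------------------
# pruning likelihood and ancestral reconstruction
# ---------------------------------------------------------------------------

def _root_prior(model: BDPModel) -> np.ndarray:
    prior = np.zeros(model.n_max + 1)
    prior[1 : model.root_max + 1] = 1.0 / model.root_max
    return prior


def _tip_vector(count: int, n_max: int) -> np.ndarray:
    if count > n_max:
        raise ValueError(f"observed count {count} exceeds n_max {n_max}")
    v = np.zeros(n_max + 1)
    v[count] = 1.0
    return v


def family_loglik(
    profile: FamilyProfile,
    tree: UltrametricTree,
    model: BDPModel,
    cache: _MatrixCache | None = None,
) -> float:
    """Log-likelihood of one family's tip counts by Felsenstein pruning."""
    profile.check_tree(tree)
    if cache is None or cache.lam != model.lambda_ or cache.n_max != model.n_max:
        cache = _MatrixCache(model.lambda_, model.n_max)
    log_scale = 0.0
    partial: dict[object, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            partial[node] = _tip_vector(profile.counts[node.taxon.label], model.n_max)
        else:
            vec = np.ones(model.n_max + 1)
            for child in node.child_nodes():
                msg = cache.get(child.edge.length) @ partial.pop(child)
                vec *= msg
            m = vec.max()
            if m <= 0.0:
                return -np.inf
            log_scale += np.log(m)
            partial[node] = vec / m
    root_lik = float(_root_prior(model) @ partial[tree.root])
    if root_lik <= 0.0:
        return -np.inf
    return float(np.log(root_lik) + log_scale)


def reconstruct_ancestral(
    profile: FamilyProfile,
    tree: UltrametricTree,
    model: BDPModel,
    cache: _MatrixCache | None = None,
):
    """Joint maximum-likelihood ancestral copy numbers (max-product Viterbi).

    Returns ``(states, joint_loglik)`` where ``states`` maps each internal
    node label (sorted tip set) to its ML count.  Ties break toward the
    smaller count.
    """
    profile.check_tree(tree)
    if cache is None or cache.lam != model.lambda_ or cache.n_max != model.n_max:
        cache = _MatrixCache(model.lambda_, model.n_max)
    n = model.n_max + 1
    best: dict[object, np.ndarray] = {}
    back: dict[object, np.ndarray] = {}
    log_scale: dict[object, float] = {}
    for node in tree.postorder():
        if node.is_leaf():
            best[node] = _tip_vector(profile.counts[node.taxon.label], n - 1)
            log_scale[node] = 0.0
            continue
        vec = np.ones(n)
        ls = 0.0
        for child in node.child_nodes():
            # scores[s, c] = P(c|s) * best_child[c]; max over c per parent s
            scores = cache.get(child.edge.length) * best[child][None, :]
            ptr = np.argmax(scores, axis=1)  # first max = smallest count
            vec *= scores[np.arange(n), ptr]
            back[child] = ptr
            ls += log_scale[child]
        m = vec.max()
        if m <= 0.0:
            raise ValueError("no ancestral assignment has positive probability")
        log_scale[node] = ls + np.log(m)
        best[node] = vec / m
    prior = _root_prior(model)
    root_scores = prior * best[tree.root]
    r = int(np.argmax(root_scores))
    joint = float(np.log(root_scores[r]) + log_scale[tree.root])
    states: dict[str, int] = {}
    assign: dict[object, int] = {tree.root: r}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            assign[node] = int(back[node][assign[node.parent_node]])
        if not node.is_leaf():
            states[tree.label_of(node)] = assign[node]
    return states, joint


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def fit_lambda(
    profiles: list[FamilyProfile],
    tree: UltrametricTree,
    n_max: int | None = None,
    root_max: int | None = None,
    log10_bounds: tuple[float, float] = (-6.0, 2.0),
    xtol: float = 1e-8,
):
    """Maximum-likelihood birth-death rate over a set of families.

    One lambda is shared across families; each family keeps its own uniform
    root prior sized from its largest observed count unless ``root_max`` is
    given.  Bounded scalar optimization on log10(lambda); returns
    ``(BDPModel, per-family logliks at the optimum)``.  The returned model's
    n_max/root_max are the global (largest-family) values.
    """
    if not profiles:
        raise ValueError("need at least one family profile")
    for p in profiles:
        p.check_tree(tree)
    global_max = max(p.max_count for p in profiles)
    nm = default_n_max(global_max) if n_max is None else n_max
    fam_models = [
        BDPModel(
            0.0,
            nm,
            default_root_max(p.max_count) if root_max is None else root_max,
        )
        for p in profiles
    ]

    def neg_loglik(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        cache = _MatrixCache(lam, nm)
        total = 0.0
        for p, fm in zip(profiles, fam_models):
            fm.lambda_ = lam
            total += family_loglik(p, tree, fm, cache)
        return -total

    res = minimize_scalar(
        neg_loglik, bounds=log10_bounds, method="bounded", options={"xatol": xtol}
    )
    lam_hat = 10.0**res.x
    if res.x <= log10_bounds[0] + 1e-3:
        import warnings

        warnings.warn(
            "lambda estimate at the lower bound: the data show no copy-number change",
            stacklevel=2,
        )
    cache = _MatrixCache(lam_hat, nm)
    logliks = {}
    for p, fm in zip(profiles, fam_models):
        fm.lambda_ = lam_hat
        logliks[p.name] = family_loglik(p, tree, fm, cache)
    model = BDPModel(lam_hat, nm, default_root_max(global_max) if root_max is None else root_max)
    return model, logliks


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def branch_shift_pvalue(
    s: int, c: int, t: float, lam: float, n_max: int | None = None
) -> float:
    """Exact two-sided tail test for a parent->child transition.

    p = sum over child states c' of P(c'|s,t) where P(c'|s,t) <= P(c|s,t);
    the observed transition always contributes, so p in (0, 1].  t is in My.
    """
    nm = default_n_max(max(s, c)) if n_max is None else n_max
    row = transition_matrix(t, lam, nm)[s]
    pc = row[c]
    return float(row[row <= pc * (1.0 + 1e-12)].sum())


def simulate_profiles(
    tree: UltrametricTree,
    model: BDPModel,
    n: int,
    seed: int | np.random.Generator,
    name_prefix: str = "sim",
) -> list[FamilyProfile]:
    """Forward-simulate families: root from the uniform prior, then per-branch
    sampling from the transition kernel down the tree."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cache = _MatrixCache(model.lambda_, model.n_max)
    out = []
    states = np.arange(model.n_max + 1)
    for i in range(n):
        counts: dict[object, int] = {}
        assign: dict[object, int] = {}
        for node in tree.preorder():
            if node is tree.root:
                assign[node] = int(rng.integers(1, model.root_max + 1))
            else:
                row = cache.get(node.edge.length)[assign[node.parent_node]]
                row = row / row.sum()
                assign[node] = int(rng.choice(states, p=row))
            if node.is_leaf():
                counts[node.taxon.label] = assign[node]
        # simulated families may go extinct everywhere; bypass the observed-
        # data invariant (at least one positive count) for those draws
        prof = FamilyProfile.__new__(FamilyProfile)
        object.__setattr__(prof, "name", f"{name_prefix}{i}")
        object.__setattr__(prof, "counts", counts)
        out.append(prof)
    return out


def family_conservation_pvalue(
    profile: FamilyProfile,
    tree: UltrametricTree,
    model: BDPModel,
    n_sim: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte Carlo family-wide conservation test.

    Simulates ``n_sim`` families under the fitted model and reports the
    fraction whose likelihood falls at or below the observed family's, with a
    (count+1)/(n_sim+1) correction so p is never exactly zero.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives an unstable p-value estimate")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cache = _MatrixCache(model.lambda_, model.n_max)
    obs = family_loglik(profile, tree, model, cache)
    sims = simulate_profiles(tree, model, n_sim, rng)
    count = 0
    for sp in sims:
        ll = family_loglik(sp, tree, model, cache)
        if ll <= obs + 1e-12:
            count += 1
    return (count + 1) / (n_sim + 1)


# ---------------------------------------------------------------------------
# subsampling robustness
# ---------------------------------------------------------------------------

def _star_tree(tree: UltrametricTree, k: int, eps_ky: float) -> UltrametricTree:
    """Expand each species tip into a star of k individual tips at eps_ky."""
    parts = _star_newick(tree.root, tree, k, eps_ky)
    return parse_newick(parts + ";")


def _star_newick(node, tree: UltrametricTree, k: int, eps_ky: float) -> str:
    if node.is_leaf():
        sp = node.taxon.label
        tips = ",".join(f"{sp}__{i}:{eps_ky}" for i in range(k))
        length = node.edge.length - eps_ky
        if length <= 0:
            raise ValueError("eps_ky must be smaller than every terminal branch")
        return f"({tips}):{length}"
    inner = ",".join(_star_newick(ch, tree, k, eps_ky) for ch in node.child_nodes())
    if node.parent_node is None:
        return f"({inner})"
    return f"({inner}):{node.edge.length}"


def subsample_robustness(
    table,
    tree: UltrametricTree,
    k: int = 5,
    reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05 / BRANCH_TEST_DIVISOR,
    eps_ky: float = 1.0,
) -> pd.DataFrame:
    """Branch-test support counts under repeated subsampling of individuals.

    Per replicate: draw ``k`` individuals per species without replacement,
    attach them as a star (branch length ``eps_ky``) below the species node,
    refit lambda on the expanded tree, run branch-shift tests on the original
    species-level branches, and count replicates significant at ``alpha``.
    ``table`` is a :class:`famevol.stats.CopyNumberTable`.

    Returns a DataFrame indexed by (family, branch) with a ``support`` column.
    """
    sizes = table.species_sizes()
    too_small = sorted(sp for sp, nsp in sizes.items() if nsp < k)
    if too_small:
        raise ValueError(f"species with fewer than k={k} individuals: {too_small}")
    rng = np.random.default_rng(seed)
    star = _star_tree(tree, k, eps_ky)
    families = list(table.families)
    support: dict[tuple[str, str], int] = {}
    for _rep in range(reps):
        chosen: dict[str, list] = {
            sp: list(rng.choice(table.individuals_of(sp), size=k, replace=False))
            for sp in sizes
        }
        profiles = []
        for fam in families:
            counts = {}
            for sp, ids in chosen.items():
                for i, ind in enumerate(ids):
                    counts[f"{sp}__{i}"] = int(np.floor(table.value(ind, fam) + 0.5))
            if max(counts.values()) == 0:
                continue  # family absent in this draw; nothing to test
            profiles.append(FamilyProfile(fam, counts))
        model, _ = fit_lambda(profiles, star)
        for prof in profiles:
            states, _ = reconstruct_ancestral(prof, star, model)
            for node, t_ky in star.branches():
                label = star.label_of(node)
                if node.is_leaf():
                    continue  # individual tips: not species-level branches
                child_tips = {lf.taxon.label for lf in node.leaf_iter()}
                species_of = {lbl.split("__")[0] for lbl in child_tips}
                parent = node.parent_node
                parent_label = star.label_of(parent)
                child_count = states[label]
                parent_count = (
                    states[parent_label]
                    if parent_label in states
                    else None
                )
                if parent_count is None:
                    continue
                p = branch_shift_pvalue(
                    parent_count, child_count, t_ky / KY_PER_MY, model.lambda_, model.n_max
                )
                branch_name = (
                    sorted(species_of)[0] if len(species_of) == 1 else "(" + ",".join(sorted(species_of)) + ")"
                )
                key = (prof.name, branch_name)
                support.setdefault(key, 0)
                if p < alpha:
                    support[key] += 1
    rows = [
        {"family": fam, "branch": br, "support": cnt, "reps": reps}
        for (fam, br), cnt in sorted(support.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class CopyNumberEvolutionModel:
    """Birth-death copy-number evolution model over a family set.

    Parameters
    ----------
    profiles : list of FamilyProfile
        Per-species copy-number medians, one per gene family.
    tree : UltrametricTree
        Time-calibrated species tree (branch lengths in ky).
    """

    def __init__(self, profiles, tree, n_max=None, root_max=None):
        self.profiles = list(profiles)
        self.tree = tree
        self.n_max = n_max
        self.root_max = root_max

    @classmethod
    def from_dataframe(cls, medians: pd.DataFrame, tree, **kw):
        """Build from a species x family DataFrame of (possibly real-valued)
        medians; values are rounded half up."""
        profiles = []
        for fam in medians.columns:
            col = medians[fam]
            if col.isna().any():
                continue
            counts = {sp: int(np.floor(v + 0.5)) for sp, v in col.items()}
            profiles.append(FamilyProfile(str(fam), counts))
        return cls(profiles, tree, **kw)

    def fit(self, **kw) -> "CopyNumberEvolutionResults":
        model, logliks = fit_lambda(
            self.profiles, self.tree, n_max=self.n_max, root_max=self.root_max, **kw
        )
        return CopyNumberEvolutionResults(self, model, logliks)


class CopyNumberEvolutionResults:
    """Fitted birth-death model: rate estimate, reconstructions and tests."""

    def __init__(self, model_spec: CopyNumberEvolutionModel, model: BDPModel, logliks):
        self.spec = model_spec
        self.model = model
        self.lambda_ = model.lambda_
        self.logliks = logliks
        self._profiles = {p.name: p for p in model_spec.profiles}

    def _family_model(self, profile: FamilyProfile) -> BDPModel:
        return BDPModel(
            self.lambda_,
            self.model.n_max,
            default_root_max(profile.max_count)
            if self.spec.root_max is None
            else self.spec.root_max,
        )

    def ancestral_states(self, family: str) -> dict[str, int]:
        prof = self._profiles[family]
        states, _ = reconstruct_ancestral(prof, self.spec.tree, self._family_model(prof))
        return states

    def branch_tests(self, family: str) -> pd.DataFrame:
        """Per-branch shift p-values using reconstructed ancestral counts."""
        prof = self._profiles[family]
        fam_model = self._family_model(prof)
        states, _ = reconstruct_ancestral(prof, self.spec.tree, fam_model)
        tree = self.spec.tree
        rows = []
        for node, t_ky in tree.branches():
            child_label = tree.label_of(node)
            parent_label = tree.label_of(node.parent_node)
            child = (
                prof.counts[child_label] if node.is_leaf() else states[child_label]
            )
            parent = states[parent_label]
            p = branch_shift_pvalue(
                parent, child, t_ky / KY_PER_MY, self.lambda_, fam_model.n_max
            )
            rows.append(
                {
                    "family": family,
                    "branch": child_label,
                    "parent_count": parent,
                    "child_count": child,
                    "length_ky": t_ky,
                    "pvalue": p,
                }
            )
        return pd.DataFrame(rows)

    def family_pvalues(self, n_sim: int = 1000, seed: int = 0) -> pd.Series:
        rng = np.random.default_rng(seed)
        out = {}
        for name, prof in self._profiles.items():
            out[name] = family_conservation_pvalue(
                prof, self.spec.tree, self._family_model(prof), n_sim=n_sim, seed=rng
            )
        return pd.Series(out, name="pvalue")

    def simulate(self, n: int, seed: int = 0) -> list[FamilyProfile]:
        return simulate_profiles(self.spec.tree, self.model, n, seed)

    def summary(self) -> str:
        lines = [
            "Copy-number birth-death model",
            "=" * 45,
            f"families:          {len(self._profiles)}",
            f"tree tips:         {self.spec.tree.n_tips}",
            f"lambda (per My):   {self.lambda_:.6f}",
            f"n_max:             {self.model.n_max}",
            f"total loglik:      {sum(self.logliks.values()):.4f}",
            "-" * 45,
            f"{'family':<12}{'loglik':>12}",
        ]
        for name, ll in self.logliks.items():
            lines.append(f"{name:<12}{ll:>12.4f}")
        return "\n".join(lines)
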