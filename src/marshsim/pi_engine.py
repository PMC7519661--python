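"""Buckingham-pi derivation with exact rational arithmetic.

A system of n dimensional variables over r independent fundamental
dimensions reduces to n - r independent dimensionless groups.  Each group is
built by raising r "repeating" variables to unknown exponents against one
target variable (held at exponent +1) and solving the dimensional
homogeneity system exactly.  For the salt-marsh system (nee, par, st, ss,
pa, cp, t over M, L, T, K) this yields the light-use-efficiency number
LUE = nee/par and a family of environmental driver numbers, of which the
biogeochemical number BGC = st·cp·ss/pa is the one the response ultimately
collapses onto.

All exponent arithmetic uses ``fractions.Fraction`` so that equivalence and
uniqueness tests (groups related by powers, roots, or inversion are the same
similitude) are exact.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .dimensions import VARIABLES, DimensionVector, PhysicalVariable

__all__ = [
    "PiGroup",
    "InvalidRepeatingSetError",
    "dimension_matrix",
    "validate_repeating_set",
    "solve_pi",
    "derive_all",
    "combine",
    "is_equivalent",
    "unique_drivers",
    "enumerate_repeating_sets",
    "eq14_candidate_pool",
    "canonical_drivers",
    "express_in_basis",
    "pi_groups_to_json",
    "pi_groups_from_json",
]

_N_DIMS = 4  # M, L, T, K


class InvalidRepeatingSetError(ValueError):
    """The chosen repeating variables do not span the dimension space."""


def _frac(x) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(x)


@dataclass(frozen=True)
class PiGroup:
    """A monomial ∏ varᵉ over named variables with exact rational exponents.

    Zero exponents are dropped from the map; the empty map is unity.
    """

    exponents: Mapping[str, Fraction] = field(default_factory=dict)
    label: Optional[str] = None

    def __post_init__(self):
        clean = {k: _frac(v) for k, v in self.exponents.items() if _frac(v) != 0}
        object.__setattr__(self, "exponents", dict(sorted(clean.items())))

    # -- algebra ------------------------------------------------------------

    def __mul__(self, other: "PiGroup") -> "PiGroup":
        exps = dict(self.exponents)
        for k, v in other.exponents.items():
            exps[k] = exps.get(k, Fraction(0)) + v
        return PiGroup(exps)

    def __truediv__(self, other: "PiGroup") -> "PiGroup":
        return self * other ** -1

    def __pow__(self, q) -> "PiGroup":
        q = _frac(q)
        return PiGroup({k: v * q for k, v in self.exponents.items()})

    # -- dimensional checks -------------------------------------------------

    def dimension(self, variables: Mapping[str, PhysicalVariable] = VARIABLES
                  ) -> DimensionVector:
        dim = DimensionVector()
        for name, e in self.exponents.items():
            dim = dim + variables[name].dimension.scale(e)
        return dim

    def is_dimensionless(self, variables: Mapping[str, PhysicalVariable] = VARIABLES
                         ) -> bool:
        return self.dimension(variables).is_zero

    # -- canonical form -----------------------------------------------------

    def canonical(self) -> tuple:
        """Primitive-integer canonical exponent vector.

        Divide by the exponent of the lexicographically first variable with a
        nonzero exponent (so equivalence under powers, roots, and inversion
        collapses), clear denominators, and reduce — the leading exponent
        comes out positive.  Unity canonicalizes to the empty tuple.
        """
        if not self.exponents:
            return ()
        names = sorted(self.exponents)
        lead = self.exponents[names[0]]
        scaled = [self.exponents[n] / lead for n in names]
        lcm = 1
        for f in scaled:
            lcm = lcm * f.denominator // math.gcd(lcm, f.denominator)
        ints = [int(f * lcm) for f in scaled]
        g = 0
        for i in ints:
            g = math.gcd(g, abs(i))
        ints = [i // g for i in ints]
        return tuple(zip(names, ints))

    # -- numeric evaluation ---------------------------------------------------

    def evaluate(self, data: Mapping[str, "np.ndarray | float"],
                 constants: Optional[Mapping[str, float]] = None):
        """Evaluate the monomial on numeric values (arrays broadcast)."""
        result = 1.0
        for name, e in self.exponents.items():
            if name in data:
                v = data[name]
            elif constants and name in constants:
                v = constants[name]
            else:
                raise KeyError(f"no value supplied for variable {name!r}")
            result = result * np.asarray(v, dtype=float) ** float(e)
        return result

    def __str__(self) -> str:
        if not self.exponents:
            return "1"
        num = [f"{n}^{e}" if e != 1 else n for n, e in self.exponents.items() if e > 0]
        den = [f"{n}^{-e}" if e != -1 else n for n, e in self.exponents.items() if e < 0]
        s = "·".join(num) or "1"
        if den:
            s += " / (" + "·".join(den) + ")"
        return s


# ---------------------------------------------------------------------------
# Exact linear algebra over Fractions (Gaussian elimination)

def dimension_matrix(variables: Sequence[PhysicalVariable]):
    """Dimension matrix with row order (M, L, T, K); column j = variable j."""
    if not variables:
        raise ValueError("need at least one variable")
    return [[v.dimension.as_tuple()[row] for v in variables] for row in range(_N_DIMS)]


def _rref(matrix):
    """Reduced row-echelon form over Fractions; returns (rref, pivot_cols)."""
    m = [[_frac(x) for x in row] for row in matrix]
    rows, cols = len(m), len(m[0]) if m else 0
    pivots = []
    r = 0
    for c in range(cols):
        pivot = next((i for i in range(r, rows) if m[i][c] != 0), None)
        if pivot is None:
            continue
        m[r], m[pivot] = m[pivot], m[r]
        lead = m[r][c]
        m[r] = [x / lead for x in m[r]]
        for i in range(rows):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == rows:
            break
    return m, pivots


def _rank(matrix) -> int:
    return len(_rref(matrix)[1])


def _null_space_vector(matrix):
    """One rational null-space vector of a column-deficient matrix, or None."""
    rref, pivots = _rref(matrix)
    cols = len(matrix[0])
    free = [c for c in range(cols) if c not in pivots]
    if not free:
        return None
    f = free[0]
    vec = [Fraction(0)] * cols
    vec[f] = Fraction(1)
    for row, p in zip(rref, pivots):
        vec[p] = -row[f]
    return vec


def _solve_exact(A, b):
    """Solve a square rational system exactly; raises on singularity."""
    n = len(b)
    aug = [list(A[i]) + [b[i]] for i in range(n)]
    rref, pivots = _rref(aug)
    if pivots == list(range(n)):
        return [rref[i][n] for i in range(n)]
    # Inconsistent or underdetermined.
    raise InvalidRepeatingSetError("singular homogeneity system")


# ---------------------------------------------------------------------------
# Buckingham-pi operations

def validate_repeating_set(names: Sequence[str],
                           variables: Mapping[str, PhysicalVariable] = VARIABLES):
    """Check that r = 4 repeating variables span (M, L, T, K).

    Returns ``(ok, diagnostic)``; when invalid the diagnostic names a
    dimensionless combination the set forms among itself (the null-space
    witness), which is exactly the paper-style reason a set is rejected.
    """
    if len(names) != _N_DIMS:
        raise ValueError(f"repeating set must have exactly {_N_DIMS} members, "
                         f"got {len(names)}")
    if len(set(names)) != len(names):
        raise ValueError("repeating set contains duplicates")
    mat = dimension_matrix([variables[n] for n in names])
    if _rank(mat) == _N_DIMS:
        return True, None
    vec = _null_space_vector(mat)
    combo = PiGroup({n: e for n, e in zip(names, vec)})
    return False, f"set forms the dimensionless combination {combo}"


def solve_pi(repeating: Sequence[str], target: str,
             variables: Mapping[str, PhysicalVariable] = VARIABLES,
             label: Optional[str] = None) -> PiGroup:
    """Solve the homogeneity system for one pi group.

    The target variable enters with exponent +1; the four repeating-variable
    exponents solve  D_repeating · x = −d_target  exactly, where D is the
    (M, L, T, K) dimension matrix.
    """
    ok, diag = validate_repeating_set(repeating, variables)
    if not ok:
        raise InvalidRepeatingSetError(diag)
    if target in repeating:
        raise ValueError(f"target {target!r} must not be a repeating variable")
    A = dimension_matrix([variables[n] for n in repeating])
    d_target = variables[target].dimension.as_tuple()
    b = [-x for x in d_target]
    x = _solve_exact(A, b)
    exps = {n: e for n, e in zip(repeating, x)}
    exps[target] = Fraction(1)
    group = PiGroup(exps, label=label)
    assert group.is_dimensionless(variables)
    return group


def derive_all(var_names: Sequence[str], repeating: Sequence[str],
               variables: Mapping[str, PhysicalVariable] = VARIABLES) -> list:
    """One pi group per non-repeating variable: exactly n − r groups."""
    return [solve_pi(repeating, name, variables)
            for name in var_names if name not in repeating]


def combine(a: PiGroup, b: PiGroup, op: str = "multiply") -> PiGroup:
    """Combine two dimensionless groups into a new one (product or ratio)."""
    if op == "multiply":
        return a * b
    if op == "divide":
        return a / b
    raise ValueError(f"unknown op {op!r}")


def is_equivalent(a: PiGroup, b: PiGroup) -> bool:
    """True iff the exponent vectors are proportional by a nonzero rational.

    This identifies a group with its powers, roots, and inverse — e.g.
    ss²·st·cp/par² and ss·√(st·cp)/par are the same similitude.
    """
    return a.canonical() == b.canonical()


def unique_drivers(groups: Iterable[PiGroup]) -> list:
    """Deduplicate by equivalence class, preserving first occurrence."""
    seen = set()
    out = []
    for g in groups:
        key = g.canonical()
        if key not in seen:
            seen.add(key)
            out.append(g)
    return out


def enumerate_repeating_sets(candidates: Sequence[str],
                             variables: Mapping[str, PhysicalVariable] = VARIABLES,
                             max_sets: Optional[int] = None) -> list:
    """All valid 4-subsets of the candidate variables, in lexicographic order."""
    out = []
    for combo in itertools.combinations(sorted(candidates), _N_DIMS):
        ok, _ = validate_repeating_set(combo, variables)
        if ok:
            out.append(tuple(combo))
            if max_sets is not None and len(out) >= max_sets:
                break
    return out


# ---------------------------------------------------------------------------
# The salt-marsh driver pool

#: Canonical repeating set used in the main derivation.
CANONICAL_REPEATING = ("par", "st", "ss", "t")

DRIVER_CANDIDATES = ("par", "st", "ss", "pa", "cp", "t")  # response nee excluded


def eq14_candidate_pool(variables: Mapping[str, PhysicalVariable] = VARIABLES,
                        response: str = "nee") -> list:
    """Candidate pool of environmental driver groups.

    Iterates every valid repeating set of the six driver variables, derives
    the pi group of each left-out driver (the response group is not a
    driver), then augments the pool with the products and ratios of the
    first environmental number (ss·pa/par², from the canonical iteration)
    with each unique iterated driver — the combination step that produces
    the remaining printed groups.  Deduplication of this pool yields the six
    unique driver numbers.
    """
    pool = []
    for rep in enumerate_repeating_sets(DRIVER_CANDIDATES, variables):
        for target in DRIVER_CANDIDATES:
            if target not in rep:
                pool.append(solve_pi(rep, target, variables))
    anchor = solve_pi(CANONICAL_REPEATING, "pa", variables)  # ss·pa/par²
    for g in unique_drivers(pool):
        pool.append(anchor * g)
        pool.append(anchor / g)
    # The trivial group (unity, from anchor/anchor) is not a driver.
    return [g for g in pool if g.exponents]


def canonical_drivers(variables: Mapping[str, PhysicalVariable] = VARIABLES) -> dict:
    """The named pi groups of the analysis, derived (not transcribed).

    Returns a dict with keys ``lue`` (response nee/par), ``pi2``
    (ss·pa/par²), ``pi3`` (st·cp·ss²/par²), ``pi4`` (= pi2·pi3), ``bgc``
    (= pi3/pi2 = st·cp·ss/pa), ``pi6`` (par²·st·cp/pa²), and ``pi7``
    (= pi2/pi6 = ss·pa³/(par⁴·st·cp)).
    """
    lue = solve_pi(CANONICAL_REPEATING, "nee", variables, label="lue")
    pi2 = solve_pi(CANONICAL_REPEATING, "pa", variables, label="pi2")
    pi3 = solve_pi(CANONICAL_REPEATING, "cp", variables, label="pi3")
    pi4 = PiGroup((pi2 * pi3).exponents, label="pi4")
    bgc = PiGroup((pi3 / pi2).exponents, label="bgc")
    pi6 = PiGroup(solve_pi(("par", "st", "pa", "t"), "cp", variables).exponents,
                  label="pi6")
    pi7 = PiGroup((pi2 / pi6).exponents, label="pi7")
    return {"lue": lue, "pi2": pi2, "pi3": pi3, "pi4": pi4,
            "bgc": bgc, "pi6": pi6, "pi7": pi7}


def express_in_basis(group: PiGroup, basis: Sequence[PiGroup],
                     variables: Mapping[str, PhysicalVariable] = VARIABLES):
    """Rational exponents q with  group = ∏ basisᵢ^qᵢ, or None if infeasible.

    Solves the exact linear system over the union of variable supports; used
    to check that pi sets from different repeating sets span the same space.
    """
    names = sorted({n for g in list(basis) + [group] for n in g.exponents})
    A = [[g.exponents.get(n, Fraction(0)) for g in basis] for n in names]
    b = [group.exponents.get(n, Fraction(0)) for n in names]
    # Least-structure exact solve: RREF of [A | b]; consistent iff no pivot in b.
    aug = [row + [rhs] for row, rhs in zip(A, b)]
    rref, pivots = _rref(aug)
    k = len(basis)
    if k in pivots:
        return None
    q = [Fraction(0)] * k
    for row, p in zip(rref, pivots):
        q[p] = row[k]
    # Verify (free columns may make the pivot solution inexact otherwise).
    combo = PiGroup({})
    for g, e in zip(basis, q):
        combo = combo * g ** e
    if combo.exponents != group.exponents:
        return None
    return q


# ---------------------------------------------------------------------------
# Serialization

def pi_groups_to_json(groups: Iterable[PiGroup], path=None) -> str:
    payload = [
        {"label": g.label,
         "exponents": {n: str(e) for n, e in g.exponents.items()}}
        for g in groups
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def pi_groups_from_json(source) -> list:
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                payload = json.load(fh)
    return [PiGroup({n: Fraction(e) for n, e in item["exponents"].items()},
                    label=item.get("label"))
            for item in payload]
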