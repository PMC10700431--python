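"""Parsing and manipulation of informed-hypothesis constraint strings.

An informed hypothesis restricts the category proportions of a multinomial
or independent-binomial model with equality constraints (``=``), inequality
constraints (``<`` / ``>``), free groups (``,``) and independent sections
(``&``).  Within each section the constrained elements must form a linear
chain ("stick hypotheses"); partial orders (branched hypotheses) are not
expressible in this grammar and are rejected by construction.

The canonical internal form is ascending: descending chains written with
``>`` are reversed on parse.  Internally categories are 0-based; the
user-facing dialect uses labels or 1-based indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Element",
    "RestrictionList",
    "CollapsedProblem",
    "HypothesisError",
    "parse_hypothesis",
    "split_restriction",
]

_OPERATORS = ("<", ">", "=", ",", "&")
_TOKEN_RE = re.compile(r"[<>=,&]|[^<>=,&\s]+")


class HypothesisError(ValueError):
    """Raised for malformed or contradictory hypothesis strings."""


@dataclass(frozen=True)
class Element:
    """One link of a constraint chain.

    ``parts`` holds one tuple of category indices per free member; indices
    inside a part are tied by equality.  A singleton has one part of size
    one, an equality group one part of size >= 2, and a free group several
    parts (each of which may itself be an equality-tied set, as in
    ``4, 5 = 6``).  Parts of a free group are mutually unordered but all
    bounded by the element's chain neighbours.
    """

    parts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.parts or any(not p for p in self.parts):
            raise HypothesisError("empty element in hypothesis")

    @property
    def kind(self) -> str:
        if len(self.parts) > 1:
            return "free_group"
        return "singleton" if len(self.parts[0]) == 1 else "equality_group"

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(i for part in self.parts for i in part)


@dataclass(frozen=True, eq=False)
class RestrictionList:
    """A validated informed hypothesis: independent sections of linear chains."""

    sections: tuple[tuple[Element, ...], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise HypothesisError("factor levels must be unique")
        for section in self.sections:
            if not section:
                raise HypothesisError("empty section in hypothesis")
            for element in section:
                for idx in element.members:
                    if not 0 <= idx < k:
                        raise HypothesisError(f"category index {idx} out of range")
                    if idx in seen:
                        raise HypothesisError(
                            f"category '{self.labels[idx]}' used more than once"
                        )
                    seen.add(idx)

    # -- queries ---------------------------------------------------------

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def referenced(self) -> tuple[int, ...]:
        return tuple(
            i for section in self.sections for el in section for i in el.members
        )

    def equality_groups(self) -> list[tuple[int, ...]]:
        """All equality-tied index sets (parts of size >= 2), in order."""
        return [
            part
            for section in self.sections
            for el in section
            for part in el.parts
            if len(part) >= 2
        ]

    def has_inequalities(self) -> bool:
        return any(len(section) >= 2 for section in self.sections)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RestrictionList)
            and self.sections == other.sections
            and self.labels == other.labels
        )

    # -- serialization ---------------------------------------------------

    def to_string(self) -> str:
        """Canonical (ascending) constraint string; re-parses to an equal object."""

        def fmt_el(el: Element) -> str:
            return " , ".join(
                " = ".join(self.labels[i] for i in part) for part in el.parts
            )

        return " & ".join(
            " < ".join(fmt_el(el) for el in section) for section in self.sections
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RestrictionList('{self.to_string()}')"


def _tokenize(hyp: str | Sequence[str]) -> list[str]:
    if isinstance(hyp, str):
        tokens = _TOKEN_RE.findall(hyp)
    else:
        tokens = []
        for raw in hyp:
            tokens.extend(_TOKEN_RE.findall(str(raw)))
    if not tokens:
        raise HypothesisError("empty hypothesis")
    return tokens


def _split_on(tokens: list[str], ops: tuple[str, ...]) -> tuple[list[list[str]], list[str]]:
    """Split token list on any operator in ``ops``; return chunks and the ops seen."""
    chunks: list[list[str]] = [[]]
    seen: list[str] = []
    for tok in tokens:
        if tok in ops:
            seen.append(tok)
            chunks.append([])
        else:
            chunks[-1].append(tok)
    return chunks, seen


def _resolve(token: str, labels: Sequence[str]) -> int:
    if token in labels:
        return list(labels).index(token)
    if token.isdigit():
        idx = int(token) - 1
        if 0 <= idx < len(labels):
            return idx
        raise HypothesisError(f"index {token} out of range 1..{len(labels)}")
    raise HypothesisError(f"unknown category label '{token}'")


def parse_hypothesis(
    hyp: str | Sequence[str], factor_levels: Sequence[str]
) -> RestrictionList:
    """Parse a constraint string (or token vector) into a :class:`RestrictionList`.

    Parameters
    ----------
    hyp
        Constraint in the ``< > = , &`` dialect, e.g. ``"1 > 2 = 3 > 4 , 5"``.
        Categories are referenced by label or by 1-based index.
    factor_levels
        Unique labels of all categories, in data order.

    Notes
    -----
    ``=`` binds tighter than ``,``, so ``"4 , 5 = 6"`` reads as the free pair
    {4, (5 = 6)}.  A section may use ``<`` or ``>`` but not both: mixing them
    would express a partial order, which the stick grammar cannot represent.
    """
    labels = tuple(str(lv) for lv in factor_levels)
    tokens = _tokenize(hyp)
    section_tokens, _ = _split_on(tokens, ("&",))
    sections: list[tuple[Element, ...]] = []
    for sec in section_tokens:
        if not sec:
            raise HypothesisError("empty section (stray '&')")
        el_chunks, ineqs = _split_on(sec, ("<", ">"))
        directions = set(ineqs)
        if len(directions) > 1:
            raise HypothesisError(
                "mixed '<' and '>' within one section would express a partial "
                "order; stick hypotheses must use a single direction"
            )
        elements: list[Element] = []
        for chunk in el_chunks:
            if not chunk:
                raise HypothesisError("empty element (stray inequality sign)")
            part_chunks, _ = _split_on(chunk, (",",))
            parts: list[tuple[int, ...]] = []
            for pchunk in part_chunks:
                member_chunks, _ = _split_on(pchunk, ("=",))
                members: list[int] = []
                for mchunk in member_chunks:
                    if len(mchunk) != 1:
                        raise HypothesisError(
                            f"malformed member {' '.join(mchunk) or '<empty>'}"
                        )
                    members.append(_resolve(mchunk[0], labels))
                parts.append(tuple(members))
            elements.append(Element(tuple(parts)))
        if directions == {">"}:
            elements.reverse()
        sections.append(tuple(elements))
    return RestrictionList(tuple(sections), labels)


@dataclass(frozen=True, eq=False)
class CollapsedProblem:
    """Inequality-only problem after merging equality-tied categories.

    A merged category carries the summed counts of its members and the summed
    prior concentrations minus (m - 1) for a group of size m; ``group_sizes``
    records the multiplicities, which enter the inequality constraints
    (a merged multinomial category of size m is compared through its
    per-category mean, i.e. its mass divided by m).
    """

    family: str  # 'multinomial' | 'binomial'
    x: np.ndarray
    a: np.ndarray
    restriction: RestrictionList
    group_sizes: np.ndarray
    n: np.ndarray | None = None
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("multinomial", "binomial"):
            raise ValueError(f"unknown family '{self.family}'")
        if np.any(self.a <= 0):
            raise ValueError(
                "collapsed prior concentration <= 0; the equality collapse "
                "subtracts m - 1 from the summed concentrations"
            )
        if self.family == "binomial" and (self.n is None or self.b is None):
            raise ValueError("binomial problem requires n and b")
        if self.family == "binomial" and np.any(self.b <= 0):
            raise ValueError("collapsed prior beta parameter <= 0")
        if self.restriction.equality_groups():
            raise AssertionError("collapsed restriction must be inequality-only")

    @property
    def n_categories(self) -> int:
        return len(self.x)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.restriction.labels

    @property
    def is_trivial(self) -> bool:
        """True when no section imposes an ordering (inequality BF == 1)."""
        return not self.restriction.has_inequalities()

    def target_params(self, target: str) -> tuple[np.ndarray, np.ndarray | None]:
        """(a, b) of the prior or conjugate posterior constrained density."""
        if target == "prior":
            return self.a.copy(), None if self.b is None else self.b.copy()
        if target == "posterior":
            if self.family == "multinomial":
                return self.a + self.x, None
            return self.a + self.x, self.b + self.n - self.x
        raise ValueError("target must be 'prior' or 'posterior'")

    def section_problems(self) -> list["CollapsedProblem"]:
        """One single-section subproblem per nontrivial section.

        For the multinomial family a subproblem is the Dirichlet over the
        section's categories only: by Dirichlet neutrality the within-section
        composition is itself Dirichlet and independent of the rest, so
        sections factorize.  Binomial categories are independent outright.
        """
        out = []
        for section in self.restriction.sections:
            if len(section) < 2:
                continue
            idx = [i for el in section for i in el.members]
            remap = {old: new for new, old in enumerate(idx)}
            new_sections = (
                tuple(
                    Element(tuple((remap[p[0]],) for p in el.parts))
                    for el in section
                ),
            )
            rl = RestrictionList(new_sections, tuple(self.labels[i] for i in idx))
            out.append(
                CollapsedProblem(
                    family=self.family,
                    x=self.x[idx],
                    a=self.a[idx],
                    restriction=rl,
                    group_sizes=self.group_sizes[idx],
                    n=None if self.n is None else self.n[idx],
                    b=None if self.b is None else self.b[idx],
                )
            )
        return out


def split_restriction(rl, data, prior):
    """Split a restriction into equality groups and a collapsed inequality problem.

    Parameters
    ----------
    rl : RestrictionList
    data : ordbf.conjugate.CountData
    prior : ordbf.conjugate.PriorSpec

    Returns
    -------
    (equality_groups, problem)
        ``equality_groups`` is a list of original-index tuples (each listed
        once); ``problem`` is the :class:`CollapsedProblem` over the merged
        categories, flagged trivial when the hypothesis has no inequalities.
    """
    if rl.n_categories != data.n_categories or rl.n_categories != len(prior.a):
        raise ValueError("restriction, data and prior dimensions disagree")
    equality_groups = rl.equality_groups()

    # one collapsed category per part, in order of appearance; unreferenced
    # original categories keep their own (unconstrained) collapsed category
    parts: list[tuple[int, ...]] = [
        part for section in rl.sections for el in section for part in el.parts
    ]
    referenced = set(rl.referenced())
    for i in range(rl.n_categories):
        if i not in referenced:
            parts.append((i,))

    def merge(v: np.ndarray, correct: bool) -> np.ndarray:
        out = np.array([sum(v[i] for i in part) for part in parts], dtype=float)
        if correct:
            out -= np.array([len(part) - 1 for part in parts], dtype=float)
        return out

    x_new = np.array([sum(data.x[i] for i in part) for part in parts])
    a_new = merge(np.asarray(prior.a, float), correct=True)
    sizes = np.array([len(part) for part in parts])
    labels = tuple(
        "=".join(rl.labels[i] for i in part) for part in parts
    )

    part_index = {part: j for j, part in enumerate(parts)}
    new_sections = tuple(
        tuple(
            Element(tuple((part_index[part],) for part in el.parts))
            for el in section
        )
        for section in rl.sections
    )
    new_rl = RestrictionList(new_sections, labels)

    n_new = b_new = None
    if data.n is not None:
        n_new = np.array([sum(data.n[i] for i in part) for part in parts])
        b_new = merge(np.asarray(prior.b, float), correct=True)
    problem = CollapsedProblem(
        family=prior.family,
        x=x_new,
        a=a_new,
        restriction=new_rl,
        group_sizes=sizes,
        n=n_new,
        b=b_new,
    )
    return equality_groups, problem
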