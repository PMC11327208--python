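"""Rendering procedural formulas as numbered natural-language instructions.

Translation is template-driven: every predicate has a dictionary entry
giving its surface form(s) — a noun ("leaves"), an adjective
("unobserved"), and/or a full condition clause — and operator templates
render steps, UNTIL/UNLESS conditions and GOTO loops.  Surface forms are
stored verbatim (no morphology generation); environment constants such as
the maximum reward are substituted at render time, so the same dictionary
reads "uncovers a 48" in the default environment and "uncovers a 96" in a
doubled one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .dnf2ltl import Condition, ProceduralFormula, Step, StopsApplying
from .env import EnvConfig


class TranslationError(KeyError):
    """Raised when a formula uses a predicate the dictionary does not cover."""


@dataclass
class Entry:
    """Surface forms of one predicate.

    ``noun``/``adjective`` feed the compact "they are unobserved leaves"
    style; ``clause`` is the free-standing condition ("all the roots are
    observed") used for UNTIL/UNLESS conditions and for predicates that do
    not fit the noun-phrase mould.  ``{max_reward}`` in any form is
    replaced by the environment's largest reward.
    """

    noun: Optional[str] = None
    adjective: Optional[str] = None
    clause: Optional[str] = None


@dataclass
class TranslationDictionary:
    entries: Dict[str, Entry]
    step_opener: str = "Click on the nodes satisfying all of the following conditions:"
    random_step: str = "Terminate or click on some random nodes and then terminate."
    no_click: str = "Do not click."
    until_template: str = "Repeat this step until {condition}."
    stops_template: str = "Repeat this step as long as possible."
    unless_template: str = "Click in this way unless {condition}."
    goto_template: str = "GOTO step {target} unless {condition}."

    def lookup(self, name: str) -> Entry:
        key = name
        negated = False
        if key.startswith("not(") and key.endswith(")"):
            negated = True
            key = key[4:-1]
        lookup_key = f"not({key})" if negated else key
        if lookup_key in self.entries:
            return self.entries[lookup_key]
        if negated and key in self.entries:
            # derived negation: wrap the positive clause
            base = self.entries[key]
            if base.clause is not None:
                return Entry(clause=f"it is not the case that {base.clause}")
        raise TranslationError(
            f"no translation-dictionary entry for predicate '{name}'")


def default_dictionary() -> TranslationDictionary:
    """Dictionary covering the base vocabulary, in graph-theoretic register."""
    e: Dict[str, Entry] = {
        "is_leaf": Entry(noun="leaves", clause="they are leaves"),
        "not(is_leaf)": Entry(clause="they are not leaves"),
        "is_root": Entry(noun="roots", clause="they are roots"),
        "not(is_root)": Entry(clause="they are not roots"),
        "is_observed": Entry(adjective="observed", clause="they are observed"),
        "not(is_observed)": Entry(adjective="unobserved",
                                  clause="they are unobserved"),
        "is_term": Entry(clause="planning is terminated"),
        "is_previous_observed_sibling": Entry(
            clause="the previously observed node was their sibling"),
        "not(is_previous_observed_sibling)": Entry(
            clause="the previously observed node was not their sibling"),
        "is_previous_observed_parent": Entry(
            clause="the previously observed node was their parent"),
        "is_same_branch_as_previous": Entry(
            clause="they lie on the same branch as the previously observed node"),
        "has_parent_observed": Entry(clause="their parent is observed"),
        "not(has_parent_observed)": Entry(clause="their parent is unobserved"),
        "has_child_observed": Entry(clause="one of their children is observed"),
        "is_on_best_path": Entry(clause="they lie on the best path"),
        "all_roots_observed": Entry(clause="all the roots are observed"),
        "not(all_roots_observed)": Entry(clause="not all the roots are observed"),
        "all_leaves_observed": Entry(clause="all the leaves are observed"),
        "not(all_leaves_observed)": Entry(clause="not all the leaves are observed"),
        "all_nodes_observed": Entry(clause="all the nodes are observed"),
        "is_max_observed": Entry(
            clause="the previously observed node uncovers a {max_reward}"),
        "not(is_max_observed)": Entry(
            clause="no observed node uncovers a {max_reward}"),
        "is_previous_observed_max": Entry(
            clause="the previously observed node uncovers a {max_reward}"),
        "is_positive_observed": Entry(
            clause="a positive reward is observed"),
        "is_previous_observed_positive": Entry(
            clause="the previously observed node uncovers a positive reward"),
        "is_previous_observed_leaf": Entry(
            clause="the previously observed node is a leaf"),
        "is_previous_observed_root": Entry(
            clause="the previously observed node is a root"),
        "no_observations": Entry(clause="no node is observed"),
    }
    for d in (1, 2, 3):
        level = {1: "the first level", 2: "the second level", 3: "the third level"}[d]
        e_name = f"depth_is_{d}"
        e[e_name] = Entry(clause=f"they are on {level}")
    return TranslationDictionary(entries=e)


def _subst(text: str, config: EnvConfig) -> str:
    return text.replace("{max_reward}", str(config.max_reward))


def _render_condition(cond: Condition, dictionary: TranslationDictionary,
                      config: EnvConfig) -> str:
    parts = []
    for p in sorted(cond.predicates, key=lambda q: q.name):
        entry = dictionary.lookup(p.name)
        if entry.clause is None:
            raise TranslationError(
                f"predicate '{p.name}' has no condition clause")
        parts.append(_subst(entry.clause, config))
    return " or ".join(parts)


def _render_step_body(step: Step, dictionary: TranslationDictionary,
                      config: EnvConfig) -> str:
    conj = step.conjunction
    if not conj:
        return dictionary.random_step
    if any(l.positive and l.name == "is_term" for l in conj):
        return dictionary.no_click
    nouns: List[str] = []
    adjectives: List[str] = []
    clauses: List[str] = []
    for lit in sorted(conj, key=str):
        entry = dictionary.lookup(str(lit))
        if lit.positive and entry.noun is not None:
            nouns.append(_subst(entry.noun, config))
        elif entry.adjective is not None:
            adjectives.append(_subst(entry.adjective, config))
        elif entry.clause is not None:
            clauses.append(_subst(entry.clause, config))
        else:
            raise TranslationError(f"no usable surface form for '{lit}'")
    conditions: List[str] = []
    if nouns or adjectives:
        head = " ".join(adjectives + nouns) if nouns else " and ".join(adjectives)
        conditions.append(f"they are {head}")
    conditions.extend(clauses)
    return f"{dictionary.step_opener} {'; '.join(conditions)}."


def render(procedural: ProceduralFormula, dictionary: TranslationDictionary,
           config: EnvConfig) -> str:
    """Deterministic numbered-step text for a procedural formula.

    Raises :class:`TranslationError` (naming the predicate) when the
    dictionary lacks an entry.
    """
    # the no-planning strategy reads as a bare instruction, unnumbered
    if (len(procedural.steps) == 1
            and any(l.positive and l.name == "is_term"
                    for l in procedural.steps[0].conjunction)):
        return dictionary.no_click

    lines: List[str] = []
    for k, step in enumerate(procedural.steps):
        body = _render_step_body(step, dictionary, config)
        tail: List[str] = []
        if step.unless is not None:
            tail.append(dictionary.unless_template.format(
                condition=_render_condition(step.unless, dictionary, config)))
        if isinstance(step.until, StopsApplying):
            tail.append(dictionary.stops_template)
        else:
            tail.append(dictionary.until_template.format(
                condition=_render_condition(step.until, dictionary, config)))
        if procedural.goto is not None and k == len(procedural.steps) - 1:
            tail.append(dictionary.goto_template.format(
                target=procedural.goto.target + 1,
                condition=_render_condition(procedural.goto.unless,
                                            dictionary, config)))
        lines.append(f"{k + 1}. {body} {' '.join(tail)}")
    return "\n".join(lines)
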