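"""Rule-based transcription-factor family classification from domain hits.

A family rule names the protein domains that must all be present
(``required``), those that must be absent (``forbidden``), and a priority;
classification of a protein is a pure function of its significant domain
set (hits at e-value <= 0.001): the first rule, by priority, whose
required set is contained in the domain set and whose forbidden set is
disjoint from it, supplies the family label.

The rule list itself is data.  A small example rule file covering common
grass TF families ships with the package (``data/tf_rules_example.tsv``);
it is a synthetic illustration of the rule schema, not a curated
registry export.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["TfRule", "load_rules", "example_rules", "filter_domains", "classify_tf", "tally_families"]


@dataclass(frozen=True)
class TfRule:
    family: str
    required: frozenset
    forbidden: frozenset
    priority: int
    min_copies: int = 1  # optional copy-number clause; 1 = presence only

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ValueError(f"rule {self.family}: required and forbidden sets overlap")
        if not self.required:
            raise ValueError(f"rule {self.family}: empty required set")


def _parse_set(text: str) -> frozenset:
    text = text.strip()
    if not text or text == "-":
        return frozenset()
    return frozenset(t.strip() for t in text.split(",") if t.strip())


def load_rules(path) -> list[TfRule]:
    """Read a rule TSV (family, required, forbidden, priority[, min_copies])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rules = []
    for _, r in df.iterrows():
        rules.append(
            TfRule(
                family=r["family"],
                required=_parse_set(r["required"]),
                forbidden=_parse_set(r["forbidden"]),
                priority=int(r["priority"]),
                min_copies=int(r.get("min_copies") or 1),
            )
        )
    _validate_priorities(rules)
    return sorted(rules, key=lambda r: r.priority)


def _validate_priorities(rules: Sequence[TfRule]) -> None:
    seen: dict[int, str] = {}
    for r in rules:
        if r.priority in seen and seen[r.priority] != r.family:
            raise ValueError(
                f"rules {seen[r.priority]!r} and {r.family!r} share priority {r.priority}"
            )
        seen[r.priority] = r.family


def example_rules() -> list[TfRule]:
    """The bundled example rule set (synthetic illustration of the schema)."""
    with resources.as_file(resources.files("orfeome").joinpath("data/tf_rules_example.tsv")) as p:
        return load_rules(p)


def filter_domains(
    hits: pd.DataFrame,
    evalue_max: float = 0.001,
) -> dict[str, frozenset]:
    """Significant domain sets per protein (duplicates collapse).

    ``hits`` needs columns protein_id, domain_id, evalue; rows with
    evalue <= evalue_max are kept.
    """
    for col in ("protein_id", "domain_id", "evalue"):
        if col not in hits.columns:
            raise ValueError(f"domain-hit table missing column {col!r}")
    kept = hits[hits["evalue"].astype(float) <= evalue_max]
    out: dict[str, set] = {}
    for pid, dom in zip(kept["protein_id"], kept["domain_id"]):
        out.setdefault(pid, set()).add(dom)
    return {pid: frozenset(doms) for pid, doms in out.items()}


def classify_tf(domain_set: frozenset, rules: Sequence[TfRule]) -> str | None:
    """First rule (by priority) satisfied by the domain set, or None."""
    _validate_priorities(rules)
    for rule in sorted(rules, key=lambda r: r.priority):
        if rule.required <= domain_set and not (rule.forbidden & domain_set):
            return rule.family
    return None


def tally_families(
    classifications: Mapping[str, str | None],
    fulllength_contigs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """family -> count table, with a full-length cross-tab when provided."""
    fl = set(fulllength_contigs) if fulllength_contigs is not None else None
    counts: dict[str, list[int]] = {}
    for pid, family in classifications.items():
        if family is None:
            continue
        row = counts.setdefault(family, [0, 0])
        row[0] += 1
        if fl is not None and pid in fl:
            row[1] += 1
    rows = [
        {"family": fam, "n_proteins": c[0], "n_fulllength": c[1]}
        for fam, c in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["family", "n_proteins", "n_fulllength"])
    if fl is None and not df.empty:
        df = df.drop(columns=["n_fulllength"])
    return df
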