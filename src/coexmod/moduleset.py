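"""Ordered container for co-expression gene modules.

A :class:`ModuleSet` maps module ids (``M01``, ``M02``, ...) to non-empty,
pairwise-disjoint gene lists. Ids are assigned by decreasing module size,
ties broken by the lexicographically smallest member gene, so the labelling
is a pure function of the module contents. The ``provenance`` dictionary
snapshots every parameter that produced the modules (selection, graph,
clustering, filters) so a run can be reproduced from the container alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ParameterError


def _module_sort_key(genes: Sequence[str]):
    return (-len(genes), min(genes))


@dataclass
class ModuleSet:
    modules: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mid, genes in self.modules.items():
            if not genes:
                raise ParameterError(f"module {mid} is empty")
            overlap = seen.intersection(genes)
            if overlap:
                raise ParameterError(
                    f"gene(s) {sorted(overlap)[:5]} appear in more than one module"
                )
            seen.update(genes)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_gene_lists(
        cls, gene_lists: Iterable[Sequence[str]], provenance: Mapping | None = None
    ) -> "ModuleSet":
        """Build a ModuleSet applying the canonical ordering/naming rules.

        Gene lists are sorted by decreasing size (ties: smallest member gene),
        genes within a module sorted lexicographically, and ids ``M01...``
        assigned in that order (zero-padded to at least two digits).
        """
        lists = [sorted(set(g)) for g in gene_lists if len(g)]
        lists.sort(key=_module_sort_key)
        width = max(2, len(str(len(lists))))
        modules = {f"M{i + 1:0{width}d}": genes for i, genes in enumerate(lists)}
        return cls(modules, dict(provenance or {}))

    # -- accessors -------------------------------------------------------
    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_ids(self) -> list[str]:
        return list(self.modules)

    def sizes(self) -> dict[str, int]:
        return {mid: len(genes) for mid, genes in self.modules.items()}

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.modules.values():
            out.extend(genes)
        return out

    def gene_lists(self) -> list[list[str]]:
        return [list(g) for g in self.modules.values()]

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[str]:
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> list[str]:
        return list(self.modules[module_id])

    def with_provenance(self, **extra) -> "ModuleSet":
        prov = dict(self.provenance)
        prov.update(extra)
        return ModuleSet(dict(self.modules), prov)
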