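"""Assembly quality-control gating on genome size and completeness."""

from __future__ import annotations

from dataclasses import dataclass

CVALUE_BP_PER_PG = 0.978e9  # expected bp = C-value (pg) x 0.978e9


@dataclass
class QCRecord:
    species_id: str
    assembly_size: float
    c_value: float | None
    expected_size: float | None
    busco_complete: float
    size_congruent: bool | None   # None when the C-value is unknown
    completeness_ok: bool

    @property
    def passed(self) -> bool:
        return bool(self.size_congruent) and self.completeness_ok


def qc_genome(assembly_size: float, c_value: float | None, busco_complete: float,
              size_ratio_max: float = 1.5, completeness_min: float = 0.90,
              species_id: str = "") -> QCRecord:
    """Gate an assembly on size congruence and BUSCO completeness.

    Size congruence holds when max(obs/exp, exp/obs) <= ``size_ratio_max``
    with expected size derived from the C-value; a missing C-value leaves
    the size flag unknown while completeness is still evaluated.
    """
    if assembly_size <= 0:
        raise ValueError("assembly_size must be positive")
    if not (0.0 <= busco_complete <= 1.0):
        raise ValueError("busco_complete must lie in [0, 1]")
    if size_ratio_max < 1.0:
        raise ValueError("size_ratio_max must be >= 1")
    if c_value is None:
        expected = None
        size_congruent = None
    else:
        if c_value <= 0:
            raise ValueError("c_value must be positive")
        expected = c_value * CVALUE_BP_PER_PG
        ratio = max(assembly_size / expected, expected / assembly_size)
        size_congruent = ratio <= size_ratio_max
    return QCRecord(species_id=species_id, assembly_size=assembly_size,
                    c_value=c_value, expected_size=expected,
                    busco_complete=busco_complete,
                    size_congruent=size_congruent,
                    completeness_ok=busco_complete >= completeness_min)
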