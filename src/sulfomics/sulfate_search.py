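"""ppm-based search of sulfate-labelled features against a theoretical
steroid-sulfate list, with cross-dataset consistency filtering.

Each candidate compound contributes its deprotonated-molecule m/z
(computed, never stored as input); every sulfate-labelled feature within
the ppm tolerance of a candidate yields a hit.  A feature may hit several
compounds and several features may hit one compound — manual review of
the ranked output is expected, exactly as in routine screening practice.
Hits collected over multiple administration datasets are then reduced to
the compounds observed consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem_masses import MolecularFormula, deprotonated_mz, parse_formula, ppm_delta

__all__ = [
    "TheoreticalSulfate",
    "build_theoretical_list",
    "default_compounds",
    "search",
    "consistency_filter",
    "PAPER_COMPOUNDS",
]

#: The five steroid sulfates confirmed by reference-standard matching.
PAPER_COMPOUNDS: Tuple[Tuple[str, str], ...] = (
    ("estrone sulfate", "C18H22O5S"),
    ("testosterone sulfate", "C19H28O5S"),
    ("2-methoxyestradiol sulfate", "C19H26O6S"),
    ("pregnenolone sulfate", "C21H32O5S"),
    ("cortisol sulfate", "C21H30O8S"),
)

#: Synthetic stand-in completion of the 26-entry screening list.  The
#: original screening list is unpublished beyond the five confirmed
#: compounds above, so the remaining 21 entries are common endogenous /
#: doping-relevant steroid sulfates chosen as documented placeholders.
_PLACEHOLDER_COMPOUNDS: Tuple[Tuple[str, str], ...] = (
    ("estradiol sulfate", "C18H24O5S"),
    ("estriol sulfate", "C18H24O6S"),
    ("16a-hydroxyestrone sulfate", "C18H22O6S"),
    ("2-methoxyestrone sulfate", "C19H24O6S"),
    ("dehydroepiandrosterone sulfate", "C19H28O5S"),  # isomeric with testosterone sulfate
    ("epitestosterone sulfate", "C19H28O5S"),
    ("androsterone sulfate", "C19H30O5S"),
    ("etiocholanolone sulfate", "C19H30O5S"),
    ("epiandrosterone sulfate", "C19H30O5S"),
    ("dihydrotestosterone sulfate", "C19H30O5S"),
    ("nandrolone sulfate", "C18H26O5S"),
    ("boldenone sulfate", "C19H26O5S"),
    ("trenbolone sulfate", "C18H22O5S"),
    ("epitrenbolone sulfate", "C18H22O5S"),
    ("altrenogest sulfate", "C21H26O5S"),
    ("17a-hydroxyprogesterone sulfate", "C21H30O6S"),
    ("corticosterone sulfate", "C21H30O7S"),
    ("11-deoxycortisol sulfate", "C21H30O7S"),
    ("cortisone sulfate", "C21H28O8S"),
    ("allopregnanolone sulfate", "C21H34O5S"),
    ("pregnanediol sulfate", "C21H36O5S"),
)


@dataclass(frozen=True)
class TheoreticalSulfate:
    """A named steroid sulfate with its computed [M-H]- m/z."""

    name: str
    formula: MolecularFormula
    mz: float


def build_theoretical_list(
    entries: Iterable[Tuple[str, str]],
) -> List[TheoreticalSulfate]:
    """Build the searchable list from (name, formula-string) pairs.

    Every formula must contain sulfur and at least 3 oxygens (a sulfate
    ester cannot have fewer); duplicate names are rejected.
    """
    out: List[TheoreticalSulfate] = []
    seen: Set[str] = set()
    for name, ftext in entries:
        if name in seen:
            raise ValueError(f"duplicate compound name {name!r}")
        seen.add(name)
        f = parse_formula(ftext) if isinstance(ftext, str) else ftext
        if f["S"] < 1:
            raise ValueError(f"{name}: formula {f.hill()} contains no sulfur (not a sulfate)")
        if f["O"] < 3:
            raise ValueError(f"{name}: formula {f.hill()} has fewer than 3 oxygens")
        out.append(TheoreticalSulfate(name, f, deprotonated_mz(f)))
    return out


def default_compounds() -> List[TheoreticalSulfate]:
    """The default 26-entry list: 5 confirmed compounds + 21 placeholders."""
    return build_theoretical_list(PAPER_COMPOUNDS + _PLACEHOLDER_COMPOUNDS)


def search(
    features: pd.DataFrame,
    compounds: Sequence[TheoreticalSulfate] = None,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """All (feature, compound) pairs with |Δppm| ≤ ``tol_ppm`` (inclusive).

    ``features`` is a DataFrame indexed by feature ID with ``mz`` and
    ``rt`` columns (typically the sulfate-labelled subset).  Hits are
    sorted by |Δppm|, then feature ID, then compound name — invariant to
    input ordering.
    """
    if tol_ppm < 0:
        raise ValueError("tolerance must be non-negative")
    if compounds is None:
        compounds = default_compounds()
    rows = []
    for fid, frow in features.iterrows():
        for c in compounds:
            d = ppm_delta(float(frow["mz"]), c.mz)
            if abs(d) <= tol_ppm:
                rows.append((fid, c.name, float(frow["mz"]), d, float(frow["rt"])))
    hits = pd.DataFrame(
        rows, columns=["feature_id", "compound", "observed_mz", "ppm", "rt"]
    )
    if len(hits):
        hits = hits.iloc[
            np.lexsort((hits["compound"], hits["feature_id"], np.abs(hits["ppm"])))
        ].reset_index(drop=True)
    return hits


def consistency_filter(
    hit_sets: Mapping[str, pd.DataFrame],
    min_datasets: int,
) -> Tuple[List[str], pd.DataFrame]:
    """Keep compounds hit in at least ``min_datasets`` datasets.

    ``hit_sets`` maps dataset name to that dataset's hit table (as from
    :func:`search`).  Returns the retained compound names (sorted) and
    the full compound x dataset presence matrix.
    """
    if not hit_sets:
        raise ValueError("need at least one dataset")
    if min_datasets > len(hit_sets):
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {len(hit_sets)} datasets provided"
        )
    names = sorted(hit_sets)
    all_compounds = sorted({c for h in hit_sets.values() for c in h["compound"]})
    presence = pd.DataFrame(False, index=all_compounds, columns=names)
    for ds in names:
        for c in set(hit_sets[ds]["compound"]):
            presence.loc[c, ds] = True
    retained = [c for c in all_compounds if int(presence.loc[c].sum()) >= min_datasets]
    return retained, presence
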