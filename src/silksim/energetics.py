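"""Incorporation-energy bookkeeping and water-site ranking.

The incorporation energy of a guest (here a water molecule) in a host lattice is

    E_inc = E(host + guest) - E(host) - E(guest)

with all three energies on a common reference.  Negative E_inc means a thermodynamic
driving force for uptake of the guest at that site; positive means the site is
unfavorable.  The three energies come from external engines or synthetic data — this
module only does the bookkeeping, ranking and CSV round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["EnergyTriple", "incorporation_energy", "rank_sites",
           "read_triples_csv", "write_ranking_csv"]


@dataclass(frozen=True)
class EnergyTriple:
    """Energies (kJ/mol, common reference) of complex, host and guest for one site."""

    site: str
    e_complex: float     # silk + water
    e_host: float        # dehydrated silk
    e_guest: float       # isolated water

    def __post_init__(self):
        for name in ("e_complex", "e_host", "e_guest"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite for site {self.site!r}")


def incorporation_energy(triple: EnergyTriple) -> float:
    """E_inc = E_complex - E_host - E_guest (kJ/mol)."""
    return triple.e_complex - triple.e_host - triple.e_guest


def rank_sites(triples) -> pd.DataFrame:
    """Rank sites by ascending incorporation energy.

    Returns a DataFrame (site, e_complex, e_host, e_guest, e_inc, favorable, rank);
    ``favorable`` is True iff E_inc < 0 (zero counts as unfavorable: no driving
    force).  Ties are broken by lexicographic site label.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("no sites to rank")
    rows = [{"site": t.site, "e_complex": t.e_complex, "e_host": t.e_host,
             "e_guest": t.e_guest, "e_inc": incorporation_energy(t)}
            for t in triples]
    df = pd.DataFrame(rows).sort_values(["e_inc", "site"], kind="stable")
    df["favorable"] = df["e_inc"] < 0.0
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def read_triples_csv(path) -> list:
    """Read EnergyTriples from CSV with columns site_id, E_complex, E_host, E_guest."""
    df = pd.read_csv(path)
    required = {"site_id", "E_complex", "E_host", "E_guest"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energy CSV missing columns: {sorted(missing)}")
    return [EnergyTriple(str(r.site_id), float(r.E_complex), float(r.E_host),
                         float(r.E_guest)) for r in df.itertuples()]


def write_ranking_csv(ranking: pd.DataFrame, path):
    out = ranking.rename(columns={"site": "site_id", "e_complex": "E_complex",
                                  "e_host": "E_host", "e_guest": "E_guest",
                                  "e_inc": "E_inc"})
    out.to_csv(path, index=False)
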