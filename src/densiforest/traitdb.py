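"""Wood density trait compilation.

Raw trait records (one measured wood density per row, tagged with a raw
taxon name and a source id) are canonicalized, averaged into species- and
genus-level lookup tables, and characterized by between-source concordance
and a nested taxonomic variance decomposition (family / genus-in-family /
species-in-genus / residual).

Genus means are means of species means, not record-weighted means, so a
single heavily sampled species cannot dominate its genus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitRecord",
    "TraitTable",
    "normalize_name",
    "build_trait_table",
    "source_concordance",
    "taxonomic_variance_decomposition",
    "read_records_tsv",
    "write_trait_table_tsv",
]

# tokens that start an authority / infraspecific tail, lowercase
_RANK_MARKERS = {"var", "var.", "subsp", "subsp.", "ssp", "ssp.", "f", "f.", "cv", "cv."}


@dataclass
class TraitRecord:
    """One wood density measurement attributed to a taxon and a source."""

    raw_name: str
    wood_density: float  # g cm^-3
    source_id: str
    canonical_species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    clade: str = "unknown"  # angiosperm | gymnosperm | unknown

    def is_valid(self) -> bool:
        return 0.0 < self.wood_density < 2.0 and bool(self.genus)


@dataclass
class TraitTable:
    """Species- and genus-level mean wood density lookup."""

    species_mean: dict[str, float]
    genus_mean: dict[str, float]
    n_records: dict[str, int] = field(default_factory=dict)
    clade: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.species_mean) + len(self.genus_mean)


def normalize_name(raw: str, synonym_map: Mapping[str, str] | None = None) -> str | None:
    """Rule-based canonical binomial (or genus-only token).

    Collapses whitespace, capitalizes the genus, lower-cases the epithet,
    strips authority strings and infraspecific rank tails, then applies the
    optional synonym map.  A single-word input yields a genus-only token.
    Returns None for empty or non-alphabetic input (rejected, logged).
    """
    if raw is None:
        return None
    tokens = raw.strip().split()
    if not tokens or not any(any(ch.isalpha() for ch in t) for t in tokens):
        logger.info("rejected unparseable taxon name: %r", raw)
        return None
    genus = tokens[0].strip()
    if not genus.replace("-", "").isalpha():
        logger.info("rejected non-alphabetic genus token: %r", raw)
        return None
    genus = genus.capitalize()
    name = genus
    if len(tokens) > 1:
        tok = tokens[1].strip()
        epithet = tok.lower()
        # epithets are written lower-case (or shouting caps in raw data);
        # a mixed-case token with a leading capital is an authority
        # ("Quercus L.", "Abies Mill.") and yields a genus-only name
        is_authority = (
            "." in tok or "(" in tok or (tok[0].isupper() and not tok.isupper())
        )
        if (
            epithet.replace("-", "").isalpha()
            and epithet not in _RANK_MARKERS
            and not is_authority
        ):
            name = f"{genus} {epithet}"
    if synonym_map:
        name = synonym_map.get(name, name)
    return name


def build_trait_table(records: Iterable[TraitRecord]) -> TraitTable:
    """Average valid records into species means, then species into genus means."""
    recs = [r for r in records]
    valid = [r for r in recs if r.is_valid()]
    n_bad = len(recs) - len(valid)
    if n_bad:
        logger.info("build_trait_table: excluded %d invalid records", n_bad)
    if not valid:
        raise ValueError("no valid trait records")

    by_species: dict[str, list[float]] = {}
    by_key_clade: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    genus_only: dict[str, list[float]] = {}
    for r in valid:
        if r.canonical_species:
            by_species.setdefault(r.canonical_species, []).append(r.wood_density)
            genus_of[r.canonical_species] = r.genus
            by_key_clade.setdefault(r.canonical_species, r.clade)
            by_key_clade.setdefault(r.genus, r.clade)
        else:
            genus_only.setdefault(r.genus, []).append(r.wood_density)
            by_key_clade.setdefault(r.genus, r.clade)

    species_mean = {sp: float(np.mean(v)) for sp, v in sorted(by_species.items())}
    n_records = {sp: len(v) for sp, v in by_species.items()}

    genus_species_means: dict[str, list[float]] = {}
    for sp, m in species_mean.items():
        genus_species_means.setdefault(genus_of[sp], []).append(m)
    # genus-only records contribute where a genus has no species-level mean
    for g, v in genus_only.items():
        genus_species_means.setdefault(g, [float(np.mean(v))])
    genus_mean = {g: float(np.mean(v)) for g, v in sorted(genus_species_means.items())}
    for g, v in genus_only.items():
        n_records[g] = n_records.get(g, 0) + len(v)
    return TraitTable(
        species_mean=species_mean,
        genus_mean=genus_mean,
        n_records=n_records,
        clade=by_key_clade,
    )


def source_concordance(
    records: Iterable[TraitRecord], min_shared: int = 3
) -> pd.DataFrame:
    """Pairwise between-source OLS concordance over shared species.

    For every ordered source pair (A, B) with at least ``min_shared``
    shared species, regresses B's species means on A's and reports the
    shared-species count, slope and R^2 = 1 - SSE/SST.  Pairs below the
    threshold are skipped with a notice.
    """
    df = pd.DataFrame(
        [
            (r.source_id, r.canonical_species, r.wood_density)
            for r in records
            if r.is_valid() and r.canonical_species
        ],
        columns=["source_id", "species", "wd"],
    )
    sources = sorted(df["source_id"].unique())
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    means = df.groupby(["source_id", "species"])["wd"].mean().unstack(level=0)
    rows = []
    for a, b in itertools.combinations(sources, 2):
        sub = means[[a, b]].dropna()
        if len(sub) < min_shared:
            logger.info("source pair (%s, %s): %d shared species, skipped", a, b, len(sub))
            continue
        x, y = sub[a].to_numpy(), sub[b].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        sst = float(np.sum((y - y.mean()) ** 2))
        sse = float(np.sum((y - pred) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        rows.append((a, b, len(sub), float(slope), r2))
    return pd.DataFrame(rows, columns=["source_a", "source_b", "n_shared", "slope", "r2"])


# ---------------------------------------------------------------------------
# nested taxonomic variance decomposition
# ---------------------------------------------------------------------------

def taxonomic_variance_decomposition(records: Iterable[TraitRecord]) -> dict[str, float]:
    """Fractions of trait variance at family / genus / species / residual level.

    Nested random-effects model
    ``y = mu + a_family + b_genus(family) + c_species(genus) + e`` estimated
    by unbalanced nested-ANOVA method of moments (Searle's expected mean
    squares), with negative component estimates truncated to zero.  Returns
    fractions of the total that sum to 1.
    """
    df = pd.DataFrame(
        [
            (r.family, r.genus, r.canonical_species or f"{r.genus} sp", r.wood_density)
            for r in records
            if r.is_valid()
        ],
        columns=["family", "genus", "species", "y"],
    )
    if df.empty:
        raise ValueError("no valid records")
    if not (df.groupby("species").size() >= 2).any():
        raise ValueError("need at least one species with >= 2 records")
    # guard against duplicated genus names across families / species across genera
    df["genus"] = df["family"] + "/" + df["genus"]
    df["species"] = df["genus"] + "/" + df["species"]

    y = df["y"].to_numpy(dtype=float)
    N = len(df)
    grand = y.mean()

    fam_sizes = df.groupby("family").size()
    gen_sizes = df.groupby("genus").size()
    sp_sizes = df.groupby("species").size()
    F, G, S = len(fam_sizes), len(gen_sizes), len(sp_sizes)

    fam_means = df.groupby("family")["y"].mean()
    gen_means = df.groupby("genus")["y"].mean()
    sp_means = df.groupby("species")["y"].mean()

    gen_of_sp = df.groupby("species")["genus"].first()
    fam_of_gen = df.groupby("genus")["family"].first()
    fam_of_sp = df.groupby("species")["family"].first()

    ss_fam = float((fam_sizes * (fam_means - grand) ** 2).sum())
    ss_gen = float(
        (gen_sizes * (gen_means - fam_means.loc[fam_of_gen].to_numpy()) ** 2).sum()
    )
    ss_sp = float(
        (sp_sizes * (sp_means - gen_means.loc[gen_of_sp].to_numpy()) ** 2).sum()
    )
    resid = y - sp_means.loc[df["species"]].to_numpy()
    ss_res = float((resid**2).sum())

    df_fam, df_gen, df_sp, df_res = F - 1, G - F, S - G, N - S

    # Searle's coefficients for unbalanced nested EMS
    sp2_by_gen = (sp_sizes**2).groupby(gen_of_sp).sum()
    sp2_by_fam = (sp_sizes**2).groupby(fam_of_sp).sum()
    gen2_by_fam = (gen_sizes**2).groupby(fam_of_gen).sum()

    def safe_div(a: float, b: float) -> float:
        return a / b if b > 0 else 0.0

    c1 = safe_div(N - float((sp2_by_gen / gen_sizes).sum()), df_sp)
    c2 = safe_div(
        float((sp2_by_gen / gen_sizes).sum()) - float((sp2_by_fam / fam_sizes).sum()),
        df_gen,
    )
    c3 = safe_div(N - float((gen2_by_fam / fam_sizes).sum()), df_gen)
    c4 = safe_div(
        float((sp2_by_fam / fam_sizes).sum()) - float((sp_sizes**2).sum()) / N, df_fam
    )
    c5 = safe_div(
        float((gen2_by_fam / fam_sizes).sum()) - float((gen_sizes**2).sum()) / N, df_fam
    )
    c6 = safe_div(N - float((fam_sizes**2).sum()) / N, df_fam)

    ms_res = safe_div(ss_res, df_res)
    ms_sp = safe_div(ss_sp, df_sp)
    ms_gen = safe_div(ss_gen, df_gen)
    ms_fam = safe_div(ss_fam, df_fam)

    var_res = max(0.0, ms_res)
    var_sp = max(0.0, safe_div(ms_sp - var_res, c1)) if df_sp > 0 else 0.0
    var_gen = (
        max(0.0, safe_div(ms_gen - var_res - c2 * var_sp, c3)) if df_gen > 0 else 0.0
    )
    var_fam = (
        max(0.0, safe_div(ms_fam - var_res - c4 * var_sp - c5 * var_gen, c6))
        if df_fam > 0
        else 0.0
    )
    if df_fam == 0:
        logger.warning("single family: family component fixed at 0")
    if df_gen == 0:
        logger.warning("single genus per family everywhere: genus component fixed at 0")

    total = var_fam + var_gen + var_sp + var_res
    if total == 0:
        return {k: 0.0 for k in ("family", "genus_within_family", "species_within_genus", "residual")}
    return {
        "family": var_fam / total,
        "genus_within_family": var_gen / total,
        "species_within_genus": var_sp / total,
        "residual": var_res / total,
    }


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "raw_name", "wood_density", "source_id", "family", "order", "clade",
]


def read_records_tsv(
    path: str | Path, synonym_map: Mapping[str, str] | None = None
) -> list[TraitRecord]:
    """Read raw trait records and canonicalize names on the way in."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        name = normalize_name(str(row.raw_name), synonym_map)
        if name is None:
            continue
        parts = name.split()
        out.append(
            TraitRecord(
                raw_name=str(row.raw_name),
                wood_density=float(row.wood_density),
                source_id=str(row.source_id),
                canonical_species=name if len(parts) == 2 else "",
                genus=parts[0],
                family=str(getattr(row, "family", "")),
                order=str(getattr(row, "order", "")),
                clade=str(getattr(row, "clade", "unknown")),
            )
        )
    return out


def write_trait_table_tsv(table: TraitTable, path: str | Path) -> None:
    rows = [
        ("species", k, v, table.n_records.get(k, 0), table.clade.get(k, "unknown"))
        for k, v in table.species_mean.items()
    ] + [
        ("genus", k, v, table.n_records.get(k, 0), table.clade.get(k, "unknown"))
        for k, v in table.genus_mean.items()
    ]
    pd.DataFrame(
        rows, columns=["level", "taxon", "wood_density", "n_records", "clade"]
    ).to_csv(path, sep="\t", index=False)
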