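"""Readers/writers, pipeline configuration and end-to-end orchestration.

Formats: MGF peak lists (read via pyteomics, written deterministically),
Newick trees (dendropy), CSV/TSV tables (pandas). Every output table
carries a comment header recording the seed and a hash of the
configuration, so a rerun with identical settings is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from . import __version__
from .dstat import bh_fdr, estimate_D
from .mk import BinaryTrait, fit_mk, sample_stochastic_maps, select_model_lrt
from .multivariate import bray_curtis_matrix, mantel_test, nmds_ordination
from .profiles import (
    AbundanceTable,
    close_composition,
    aggregate_replicates,
    presence_absence,
    within_class_percentages,
)
from .screen import LibraryConfig, ScreenConfig, Spectrum, build_library, match_spectrum
from .structures import load_registry
from .trees import Phylogeny, read_newick

log = logging.getLogger("ndmmkit")

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_clades_csv",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MGF spectra; polarity is inferred from the CHARGE sign."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pepmass = params["pepmass"]
            charge = params.get("charge")
            if charge is None:
                raise ValueError(
                    f"spectrum {params.get('title')!r} lacks a CHARGE line"
                )
            polarity = "positive" if int(charge[0]) > 0 else "negative"
            intensity = (
                float(pepmass[1])
                if len(pepmass) > 1 and pepmass[1] is not None
                else 0.0
            )
            spectra.append(
                Spectrum(
                    id=str(params.get("title", f"scan{len(spectra) + 1}")),
                    precursor_mz=float(pepmass[0]),
                    polarity=polarity,
                    peaks=list(
                        zip(entry["m/z array"], entry["intensity array"])
                    ),
                    precursor_intensity=intensity,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed formatting (byte-deterministic)."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            charge = "1+" if s.polarity == "positive" else "1-"
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(
                f"PEPMASS={s.precursor_mz:.6f} {s.precursor_intensity:.1f}\n"
            )
            fh.write(f"CHARGE={charge}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.1f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Tables and trees
# ---------------------------------------------------------------------------


def read_clades_csv(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column CSV (species, clade) -> clade name -> tip tuple."""
    df = pd.read_csv(path)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["clade"]), []).append(str(row["species"]))
    return {k: tuple(v) for k, v in out.items()}


def _write_table(
    df: pd.DataFrame,
    path: Path,
    seed: Optional[int],
    config_hash: str,
    index: bool = True,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ndmmkit {__version__} seed={seed} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths, tolerances and toggles for an end-to-end run."""

    abundance_path: str
    class_map_path: str
    tree_path: str
    clade_map_path: Optional[str] = None
    spectra_path: Optional[str] = None
    registry_path: Optional[str] = None
    outdir: str = "ndmmkit_out"
    seed: int = 0
    intensity_threshold: float = 1.0e3
    precursor_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 10.0
    n_perm_d: int = 10_000
    n_brownian_d: int = 10_000
    n_simmap: int = 100
    n_perm_mantel: int = 999
    fdr_q: float = 0.10
    run_screen: bool = True
    run_signal: bool = True
    run_ordination: bool = True
    library: LibraryConfig = field(
        default_factory=lambda: LibraryConfig(
            chain_lengths=tuple(range(3, 12)),
            unsaturated_lengths=(7,),
            omega_lengths=(3,),
            heads=("UB", "UP"),
            dimers=True,
            heads_on_dimers=True,
        )
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "library" in raw:
            lib = raw.pop("library")
            lib = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in lib.items()
            }
            raw["library"] = LibraryConfig(**lib)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in (
            "abundance_path",
            "class_map_path",
            "tree_path",
            "clade_map_path",
            "spectra_path",
            "registry_path",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(
                    f"config field {name!r}: no such file {value!r}"
                )


def _comparative_table(
    phy: Phylogeny,
    presence: pd.DataFrame,
    class_map: dict[str, str],
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound model fits, SIMMAP change counts, D statistics."""
    rows = []
    mrca_rows = []
    rng = np.random.default_rng(cfg.seed)
    clade_names = [c for c in phy.clades if c != "outgroup"]
    for compound in presence.columns:
        states = {
            sp: int(presence.loc[sp, compound]) for sp in presence.index
        }
        trait = BinaryTrait(compound, states)
        pattern = trait.pattern_class(phy)
        row: dict = {
            "NDMM": compound,
            "Class": class_map.get(compound, ""),
            "Conservation Pattern": pattern.capitalize(),
        }
        if pattern == "variable":
            er = fit_mk(phy, trait, "ER")
            ard = fit_mk(phy, trait, "ARD")
            chosen_name = select_model_lrt(er, ard)
            chosen = ard if chosen_name == "ARD" else er
            maps = sample_stochastic_maps(
                phy,
                trait,
                chosen,
                n_sim=cfg.n_simmap,
                seed=int(rng.integers(2**31)),
            )
            dres = estimate_D(
                phy,
                trait,
                n_perm=cfg.n_perm_d,
                n_brownian=cfg.n_brownian_d,
                seed=int(rng.integers(2**31)),
            )
            row.update(
                {
                    "fitMk model": chosen_name,
                    "SIMMAP changes": round(
                        float(maps.change_counts.mean()), 2
                    ),
                    "D": round(dres.D, 4),
                    "P (Ho: D = 0)": dres.p_d0,
                    "P (Ho: D = 1)": dres.p_d1,
                }
            )
            freqs = maps.node_state_frequencies()
            for clade in clade_names:
                node = phy.mrca(phy.clades[clade])
                mrca_rows.append(
                    {
                        "NDMM": compound,
                        "clade": clade,
                        "presence_probability": round(
                            float(freqs[node, 1]), 4
                        ),
                    }
                )
        else:
            row.update(
                {
                    "fitMk model": "-",
                    "SIMMAP changes": "-",
                    "D": "-",
                    "P (Ho: D = 0)": "-",
                    "P (Ho: D = 1)": "-",
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    # FDR over the two families of tests separately
    for col, flag in (
        ("P (Ho: D = 0)", "signif (D=0, FDR)"),
        ("P (Ho: D = 1)", "signif (D=1, FDR)"),
    ):
        mask = table[col] != "-"
        flags = pd.Series("-", index=table.index, dtype=object)
        if mask.any():
            flags[mask] = bh_fdr(
                table.loc[mask, col].astype(float).to_numpy(), q=cfg.fdr_q
            )
        table[flag] = flags
    mrca = pd.DataFrame(
        mrca_rows, columns=["NDMM", "clade", "presence_probability"]
    )
    return table, mrca


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run screen, profiles and comparative analyses; write result tables.

    Outputs in ``cfg.outdir``: ``screen_results.tsv`` (when spectra are
    given), ``profiles_within_class.tsv``, ``profiles_closed.tsv``,
    ``presence_matrix.tsv``, ``comparative_stats.tsv``,
    ``mrca_probabilities.tsv``, ``mantel_nmds.tsv``. Species present in
    the abundance table but missing from the tree (or vice versa) are
    dropped with a logged warning before comparative analysis.
    """
    cfg.validate_paths()
    chash = cfg.config_hash()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info(
        "ndmmkit %s pipeline: seed=%s config=%s", __version__, cfg.seed, chash
    )

    clades = (
        read_clades_csv(cfg.clade_map_path) if cfg.clade_map_path else None
    )
    phy = read_newick(cfg.tree_path, clades=clades)
    table = AbundanceTable.from_csv(cfg.abundance_path, cfg.class_map_path)

    # mirror-prune species without both profile data and a tree tip
    tree_sp = set(phy.tip_labels)
    data_sp = set(table.species)
    dropped = tree_sp ^ data_sp
    if dropped:
        log.warning(
            "dropping species without both tree and profile data: %s",
            sorted(dropped),
        )
        keep = tree_sp & data_sp
        if len(keep) < 3:
            raise ValueError("fewer than 3 species shared by tree and table")
        table = AbundanceTable(
            table.data[table.data["species"].isin(keep)].reset_index(
                drop=True
            ),
            table.class_map,
        )
        if dropped & tree_sp:
            phy = phy.prune_to(sorted(keep))

    results: dict = {"config_hash": chash}

    if cfg.run_screen and cfg.spectra_path:
        spectra = read_mgf(cfg.spectra_path)
        registry = (
            load_registry(cfg.registry_path) if cfg.registry_path else ()
        )
        lib = build_library(cfg.library, registry=registry)
        screen_cfg = ScreenConfig(
            precursor_tol_ppm=cfg.precursor_tol_ppm,
            fragment_tol_ppm=cfg.fragment_tol_ppm,
            intensity_threshold=cfg.intensity_threshold,
        )
        rows = [
            {
                "spectrum_id": r.spectrum_id,
                "candidate": "|".join(r.isomers),
                "class": r.ndmm_class,
                "adduct": r.adduct,
                "ppm": round(r.ppm, 2),
                "fragments_confirmed": r.fragments_confirmed,
                "call": r.call,
            }
            for s in spectra
            for r in match_spectrum(s, lib, screen_cfg)
        ]
        screen_df = pd.DataFrame(
            rows,
            columns=[
                "spectrum_id",
                "candidate",
                "class",
                "adduct",
                "ppm",
                "fragments_confirmed",
                "call",
            ],
        )
        _write_table(
            screen_df, outdir / "screen_results.tsv", cfg.seed, chash,
            index=False,
        )
        results["screen"] = screen_df

    means = aggregate_replicates(table)
    within = within_class_percentages(means, table.class_map)
    closed = close_composition(means)
    presence = presence_absence(table, cfg.intensity_threshold)
    _write_table(
        within.values, outdir / "profiles_within_class.tsv", cfg.seed, chash
    )
    _write_table(
        closed.values, outdir / "profiles_closed.tsv", cfg.seed, chash
    )
    _write_table(
        presence.values.astype(int),
        outdir / "presence_matrix.tsv",
        cfg.seed,
        chash,
    )
    results["profiles_within_class"] = within
    results["profiles_closed"] = closed
    results["presence"] = presence

    if cfg.run_signal:
        pres = presence.values.loc[list(phy.tip_labels)]
        stats_df, mrca_df = _comparative_table(
            phy, pres, dict(table.class_map), cfg
        )
        _write_table(
            stats_df, outdir / "comparative_stats.tsv", cfg.seed, chash,
            index=False,
        )
        _write_table(
            mrca_df, outdir / "mrca_probabilities.tsv", cfg.seed, chash,
            index=False,
        )
        results["comparative"] = stats_df
        results["mrca"] = mrca_df

    if cfg.run_ordination:
        order = list(phy.tip_labels)
        closed_ord = close_composition(means.loc[order])
        bc = bray_curtis_matrix(closed_ord)
        patristic = phy.patristic_distances()
        mantel = mantel_test(
            bc, patristic, n_perm=cfg.n_perm_mantel, seed=cfg.seed
        )
        nmds = nmds_ordination(bc, k=2, seed=cfg.seed)
        summary = pd.DataFrame(
            [
                {
                    "mantel_rho": round(mantel.rho, 4),
                    "mantel_p": mantel.p_value,
                    "mantel_n_perm": mantel.n_perm,
                    "nmds_stress": round(nmds.stress, 4),
                    "nmds_converged": nmds.converged,
                }
            ]
        )
        _write_table(
            summary, outdir / "mantel_nmds.tsv", cfg.seed, chash, index=False
        )
        coords = pd.DataFrame(
            nmds.coordinates, index=order, columns=["NMDS1", "NMDS2"]
        )
        _write_table(
            coords, outdir / "nmds_coordinates.tsv", cfg.seed, chash
        )
        results["mantel"] = mantel
        results["nmds"] = nmds

    return results
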