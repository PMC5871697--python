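"""TSV tables: MM regions, umbrella-window manifests, spectra, profiles."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..qmmm_coupling import MMRegion
from ..spectra import Spectrum

MM_COLUMNS = ["index", "element", "x", "y", "z", "q", "epsilon", "sigma", "molecule_id"]


class TableSchemaError(ValueError):
    pass


def read_mm_table(path) -> MMRegion:
    """MM sites from TSV with columns index element x y z q epsilon
    sigma molecule_id (Angstrom / e / kcal/mol / Angstrom)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return MMRegion.empty()
    header = lines[0].split()
    missing = [c for c in MM_COLUMNS if c not in header]
    if missing:
        raise TableSchemaError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    col = {c: header.index(c) for c in MM_COLUMNS}
    rows = [ln.split() for ln in lines[1:]]
    if not rows:
        return MMRegion.empty()
    get = lambda c: [r[col[c]] for r in rows]
    coords = np.array([[float(v) for v in row] for row in zip(get("x"), get("y"), get("z"))])
    return MMRegion.from_user_units(
        coords,
        [float(v) for v in get("q")],
        [float(v) for v in get("epsilon")],
        [float(v) for v in get("sigma")],
        [int(v) for v in get("molecule_id")],
        symbols=get("element"),
    )


def write_mm_table(path, mm: MMRegion) -> None:
    from ..constants import ANGSTROM_PER_BOHR, KCALMOL_PER_HARTREE

    with open(path, "w") as fh:
        fh.write("\t".join(MM_COLUMNS) + "\n")
        for i in range(mm.nsites):
            x, y, z = mm.coordinates[i] * ANGSTROM_PER_BOHR
            sym = mm.symbols[i] if mm.symbols else "X"
            fh.write(
                f"{i}\t{sym}\t{x:.10f}\t{y:.10f}\t{z:.10f}\t{mm.charges[i]:.6f}\t"
                f"{mm.lj_epsilon[i] * KCALMOL_PER_HARTREE:.6f}\t"
                f"{mm.lj_sigma[i] * ANGSTROM_PER_BOHR:.6f}\t{mm.molecule_id[i]}\n"
            )


def write_spectrum(path, spectrum: Spectrum) -> None:
    meta = spectrum.metadata
    with open(path, "w") as fh:
        if spectrum.kind == "energy_ev" and "lambda_nm" in meta:
            fh.write("# lambda_nm\tenergy_eV\tintensity_arb\n")
            for lam, ev, s in zip(meta["lambda_nm"], spectrum.abscissa, spectrum.intensity):
                fh.write(f"{lam:.6g}\t{ev:.8g}\t{s:.10g}\n")
        else:
            fh.write(f"# abscissa({spectrum.kind})\tintensity_arb\n")
            for x, s in zip(spectrum.abscissa, spectrum.intensity):
                fh.write(f"{x:.8g}\t{s:.10g}\n")


def read_spectrum(path) -> Spectrum:
    rows = np.loadtxt(path)
    if rows.shape[1] == 3:
        lam, ev, inten = rows.T
        return Spectrum(ev, inten, "energy_ev", {"lambda_nm": lam})
    return Spectrum(rows[:, 0], rows[:, 1], "")


def write_profile(path, profile) -> None:
    with open(path, "w") as fh:
        fh.write("# rc_angstrom\tF_kcalmol\terr_kcalmol\n")
        for rc, F, err in zip(profile.bin_centers, profile.free_energy, profile.uncertainty):
            fh.write(f"{rc:.8g}\t{F:.8g}\t{err:.6g}\n")


def write_series(path, times, values, header="# t_au\tvalues") -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for t, row in zip(times, values):
            fh.write("\t".join([f"{t:.10g}"] + [f"{v:.12g}" for v in np.atleast_1d(row)]) + "\n")


def read_window_manifest(path):
    """TSV rows: window_id  rc0  k_umb  series_file (path of rc series TSV)."""
    base = Path(path).parent
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        toks = ln.split()
        if len(toks) < 4:
            raise TableSchemaError(f"{path}: window rows need 4 columns")
        out.append((toks[0], float(toks[1]), float(toks[2]), str(base / toks[3])))
    return out
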