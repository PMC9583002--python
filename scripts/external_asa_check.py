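"""Check ΔASA of crystal-structure complexes against published values.

Requires network access to fetch entries from the RCSB PDB (or local
PDB files passed via --pdb-dir).  Reference buried-surface areas (Å²)
for three benchmark complexes:

    2OOB (ubiquitin / ubiquitin ligase)      ≈  808
    1GCQ (Vav / GRB2 SH3 domains)            ≈ 1207
    1BRS (barnase / barstar)                 ≈ 1555

The in-package Shrake-Rupley ASA uses NACCESS-like radii but is not
bit-compatible with NACCESS; agreement within ±5% is expected.

Usage:
    python scripts/external_asa_check.py [--pdb-dir DIR]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

REFERENCE = {
    "2OOB": {"chains": ("A", "B"), "delta_asa": 808.0},
    "1GCQ": {"chains": ("B", "C"), "delta_asa": 1207.0},
    "1BRS": {"chains": ("A", "D"), "delta_asa": 1555.0},
}


def fetch(code: str, dest: Path) -> Path:
    path = dest / f"{code.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, path)
    return path


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb-dir", type=Path, default=Path("scratch/pdb"))
    parser.add_argument("--tolerance", type=float, default=0.05)
    args = parser.parse_args()
    args.pdb_dir.mkdir(parents=True, exist_ok=True)

    from ifdyn.geometry import interface_asa
    from ifdyn.io import load_series

    failures = 0
    for code, ref in REFERENCE.items():
        path = fetch(code, args.pdb_dir)
        series = load_series(path, chain_selection=ref["chains"])
        table = interface_asa(series[0], chain_pair=ref["chains"])
        got = table.delta_asa
        rel = abs(got - ref["delta_asa"]) / ref["delta_asa"]
        status = "OK" if rel <= args.tolerance else "FAIL"
        failures += status == "FAIL"
        print(
            f"{code}: ΔASA = {got:8.1f} Å²  (reference {ref['delta_asa']:.0f}, "
            f"deviation {100 * rel:.1f}%)  {status}"
        )
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
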