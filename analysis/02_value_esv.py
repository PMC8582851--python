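#!/usr/bin/env python
"""Value the simulated landscape with the packaged coefficient table.

Reads the land-use rasters written by 01_simulate_landscape.py,
computes the per-cell, per-service ESV for each epoch, and writes
the ESV rasters plus structure tables (service x year totals with
period change rates, and per-region totals) under results/valuation/.
"""

from pathlib import Path

import pandas as pd

import esvpipe as ep

ROOT = Path(__file__).resolve().parents[1] / "results"
LANDSCAPE = ROOT / "landscape"
OUT = ROOT / "valuation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    coeffs = ep.load_coefficients()
    regions, _, _ = ep.read_raster(LANDSCAPE / "regions.tif")
    regions = regions[0].astype(int)

    years = sorted(p.stem.split("_")[1] for p in LANDSCAPE.glob("landuse_*.tif"))
    summaries, totals = [], {}
    for year in years:
        arr, spec, _ = ep.read_raster(LANDSCAPE / f"landuse_{year}.tif")
        comp = ep.LandComposition(arr.astype(float), spec, year)
        esv = ep.compute_esv(comp, coeffs)
        ep.write_raster(OUT / f"esv_{year}.tif", esv.values, spec, band_names=ep.SERVICES)
        summaries.append(ep.aggregate(esv, regions))
        totals[year] = esv.total()

    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(OUT / "esv_by_service_region_year.csv", index=False)

    structure = summary.groupby(["category", "service", "year"])["esv_yuan"].sum().unstack()
    for a, b in zip(years[:-1], years[1:]):
        structure[f"rate_{a}_{b}_pct"] = 100.0 * (structure[b] - structure[a]) / structure[a]
    structure.to_csv(OUT / "esv_structure.csv")

    print("study-wide ESV by year (billion yuan):")
    for year in years:
        print(f"  {year}: {totals[year] / 1e9:8.3f}")
    for a, b in zip(years[:-1], years[1:]):
        rate = ep.change_rate(totals[a], totals[b])
        print(f"  change {a}->{b}: {rate:+.2f}%")
    reg = summary.groupby("year")["esv_yuan"].sum()
    cat = summary[summary.category == "regulating"].groupby("year")["esv_yuan"].sum()
    print("regulating-service share by year (%):",
          ", ".join(f"{y}: {100 * cat[y] / reg[y]:.1f}" for y in years))
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
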