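"""Generate the synthetic study city's input data.

Produces five years of daily pollutant records from a monitoring network that
grows from 15 to 32 stations in 2016, district populations, baseline
mortality/morbidity rates, unit costs, and concentration-response parameters,
all under results/inputs/.
"""

from pathlib import Path

import pandas as pd

from aqhia.synthetic import SimulationConfig, write_inputs

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"

if __name__ == "__main__":
    config = SimulationConfig(seed=1)
    paths = write_inputs(config, OUT)
    stations = pd.read_csv(paths["stations"])
    print(f"wrote {len(paths)} input tables to {OUT}")
    print(f"station records: {len(stations):,} rows, "
          f"{stations['station_id'].nunique()} stations, "
          f"{stations['pollutant'].nunique()} pollutants")
    per_year = (
        stations.assign(year=pd.to_datetime(stations["date"]).dt.year)
        .groupby("year")["station_id"].nunique()
    )
    print("active stations per year:")
    print(per_year.to_string())
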