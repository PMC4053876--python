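{
  "comment": "Chinese ambient AQI breakpoint ladders (24-h average concentrations, ug/m3) for the two particulate pollutants. Editable data, not code.",
  "PM2.5": {
    "pollutant": "PM2.5",
    "pairs": [[0, 0], [35, 50], [75, 100], [115, 150], [150, 200], [250, 300], [350, 400], [500, 500]]
  },
  "PM10": {
    "pollutant": "PM10",
    "pairs": [[0, 0], [50, 50], [150, 100], [250, 150], [350, 200], [420, 300], [500, 400], [600, 500]]
  }
}
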