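<svg xmlns="http://www.w3.org/2000/svg" width="640" height="420" viewBox="0 0 640 420">
  <style>
    text { font-family: sans-serif; font-size: 14px; fill: #222222; }
    .title { font-size: 18px; font-weight: bold; }
    .node { font-weight: bold; font-size: 15px; }
    .step { font-size: 11px; fill: #555555; }
    .weight { font-size: 13px; font-weight: bold; fill: #1b5e20; }
    .weight.zero { fill: #9e9e9e; }
    .arrow { stroke: #444444; stroke-width: 1.5; fill: none; marker-end: url(#ah); }
  </style>
  <defs>
    <marker id="ah" markerWidth="9" markerHeight="9" refX="8" refY="4" orient="auto">
      <path d="M0,0 L8,4 L0,8 z" fill="#444444"/>
    </marker>
  </defs>
  <text class="title" x="20" y="30">Nitrogen cycle</text>

  <text id="node_nh4" class="node" x="60" y="120">NH4+</text>
  <text id="node_no3" class="node" x="320" y="120">NO3-</text>
  <text id="node_no2" class="node" x="560" y="120">NO2-</text>
  <text id="node_n2" class="node" x="320" y="320">N2</text>

  <path class="arrow" d="M120,115 L310,115"/>
  <text class="step" x="150" y="100">nitrification</text>
  <text id="label_nitrification" class="weight" x="185" y="135">--</text>

  <path class="arrow" d="M380,115 L550,115"/>
  <text class="step" x="400" y="100">nitrate reduction</text>
  <text id="label_nitrate_reduction" class="weight" x="440" y="135">--</text>

  <path class="arrow" d="M335,140 L330,305"/>
  <text class="step" x="350" y="220">denitrification</text>
  <text id="label_denitrification" class="weight" x="355" y="240">--</text>
</svg>
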