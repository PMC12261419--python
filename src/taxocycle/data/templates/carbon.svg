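<svg xmlns="http://www.w3.org/2000/svg" width="720" height="520" viewBox="0 0 720 520">
  <style>
    text { font-family: sans-serif; font-size: 14px; fill: #222222; }
    .title { font-size: 18px; font-weight: bold; }
    .node { font-weight: bold; font-size: 15px; }
    .step { font-size: 11px; fill: #555555; }
    .weight { font-size: 13px; font-weight: bold; fill: #b22222; }
    .weight.zero { fill: #9e9e9e; }
    .arrow { stroke: #444444; stroke-width: 1.5; fill: none; marker-end: url(#ah); }
  </style>
  <defs>
    <marker id="ah" markerWidth="9" markerHeight="9" refX="8" refY="4" orient="auto">
      <path d="M0,0 L8,4 L0,8 z" fill="#444444"/>
    </marker>
  </defs>
  <text class="title" x="20" y="30">Carbon cycle</text>

  <text id="node_organic_carbon" class="node" x="60" y="120">organic carbon</text>
  <text id="node_co2" class="node" x="340" y="120">CO2</text>
  <text id="node_ch4" class="node" x="580" y="120">CH4</text>
  <text id="node_acetate" class="node" x="340" y="320">acetate</text>
  <text id="node_ethanol" class="node" x="80" y="320">ethanol</text>
  <text id="node_h2" class="node" x="340" y="460">H2</text>
  <text id="node_h2o" class="node" x="580" y="460">H2O</text>

  <path class="arrow" d="M185,115 L330,115"/>
  <text class="step" x="200" y="100">organic carbon oxidation</text>
  <text id="label_organic_carbon_oxidation" class="weight" x="230" y="135">--</text>

  <path class="arrow" d="M390,115 L570,115"/>
  <text class="step" x="420" y="100">methanogenesis (CO2 + H2)</text>
  <text id="label_methanogenesis" class="weight" x="465" y="135">--</text>

  <path class="arrow" d="M370,140 C400,220 400,250 380,310"/>
  <text class="step" x="400" y="230">acetogenesis (Wood-Ljungdahl)</text>
  <text id="label_acetogenesis_wood_ljungdahl" class="weight" x="410" y="248">--</text>

  <path class="arrow" d="M350,305 C320,250 320,200 345,140"/>
  <text class="step" x="220" y="230">acetate oxidation</text>
  <text id="label_acetate_oxidation" class="weight" x="250" y="248">--</text>

  <path class="arrow" d="M110,135 C160,220 230,290 325,318"/>
  <text class="step" x="130" y="250">fermentation</text>
  <text id="label_fermentation" class="weight" x="140" y="268">--</text>

  <path class="arrow" d="M140,325 L330,325"/>
  <text class="step" x="170" y="345">ethanol oxidation</text>
  <text id="label_ethanol_oxidation" class="weight" x="200" y="362">--</text>

  <path class="arrow" d="M90,135 C120,300 220,420 328,456"/>
  <text class="step" x="120" y="420">hydrogen generation</text>
  <text id="label_hydrogen_generation" class="weight" x="150" y="438">--</text>

  <path class="arrow" d="M375,455 L570,455"/>
  <text class="step" x="410" y="440">hydrogen oxidation</text>
  <text id="label_hydrogen_oxidation" class="weight" x="445" y="478">--</text>
</svg>
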