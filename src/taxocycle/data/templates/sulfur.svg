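<svg xmlns="http://www.w3.org/2000/svg" width="640" height="420" viewBox="0 0 640 420">
  <style>
    text { font-family: sans-serif; font-size: 14px; fill: #222222; }
    .title { font-size: 18px; font-weight: bold; }
    .node { font-weight: bold; font-size: 15px; }
    .step { font-size: 11px; fill: #555555; }
    .weight { font-size: 13px; font-weight: bold; fill: #4a148c; }
    .weight.zero { fill: #9e9e9e; }
    .arrow { stroke: #444444; stroke-width: 1.5; fill: none; marker-end: url(#ah); }
  </style>
  <defs>
    <marker id="ah" markerWidth="9" markerHeight="9" refX="8" refY="4" orient="auto">
      <path d="M0,0 L8,4 L0,8 z" fill="#444444"/>
    </marker>
  </defs>
  <text class="title" x="20" y="30">Sulfur cycle (with accessory metal reduction)</text>

  <text id="node_so4" class="node" x="80" y="140">SO4 2-</text>
  <text id="node_h2s" class="node" x="480" y="140">H2S</text>
  <text id="node_fe3" class="node" x="80" y="340">Fe(III)</text>
  <text id="node_fe2" class="node" x="480" y="340">Fe(II)</text>

  <path class="arrow" d="M160,125 C280,80 360,80 470,125"/>
  <text class="step" x="260" y="85">sulfate reduction</text>
  <text id="label_sulfate_reduction" class="weight" x="295" y="115">--</text>

  <path class="arrow" d="M470,155 C360,200 280,200 160,155"/>
  <text class="step" x="260" y="215">sulfur oxidation</text>
  <text id="label_sulfur_oxidation" class="weight" x="295" y="190">--</text>

  <path class="arrow" d="M150,335 L470,335"/>
  <text class="step" x="240" y="320">iron reduction</text>
  <text id="label_iron_reduction" class="weight" x="285" y="358">--</text>
</svg>
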