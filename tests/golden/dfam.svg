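<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="800.000" height="120.000" viewBox="0 0 800.000 120.000">
  <defs/>
  <rect class="background" x="0.000" y="0.000" width="800.000" height="120.000" fill="#ffffff"/>
  <g id="axis">
    <line x1="4.000" y1="18.000" x2="796.000" y2="18.000" stroke="#444444" stroke-width="1"/>
    <line x1="4.000" y1="18.000" x2="4.000" y2="22.000" stroke="#444444" stroke-width="1"/>
    <text x="4.000" y="15.000" text-anchor="middle" font-size="9" fill="#444444">0</text>
    <line x1="162.400" y1="18.000" x2="162.400" y2="22.000" stroke="#444444" stroke-width="1"/>
    <text x="162.400" y="15.000" text-anchor="middle" font-size="9" fill="#444444">20000</text>
    <line x1="320.800" y1="18.000" x2="320.800" y2="22.000" stroke="#444444" stroke-width="1"/>
    <text x="320.800" y="15.000" text-anchor="middle" font-size="9" fill="#444444">40000</text>
    <line x1="479.200" y1="18.000" x2="479.200" y2="22.000" stroke="#444444" stroke-width="1"/>
    <text x="479.200" y="15.000" text-anchor="middle" font-size="9" fill="#444444">60000</text>
    <line x1="637.600" y1="18.000" x2="637.600" y2="22.000" stroke="#444444" stroke-width="1"/>
    <text x="637.600" y="15.000" text-anchor="middle" font-size="9" fill="#444444">80000</text>
  </g>
  <g id="layer-forward-tes">
    <rect id="forward-tes-syn7-11-1" x="121.968" y="25.600" width="6.589" height="12.800" fill="#7570b3" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-7-2" x="158.638" y="25.600" width="21.146" height="12.800" fill="#7570b3" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-4-3" x="171.959" y="41.600" width="11.920" height="12.800" fill="#e6ab02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-13-4" x="191.451" y="25.600" width="9.520" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-8-5" x="212.344" y="25.600" width="13.424" height="12.800" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-2-6" x="238.036" y="25.600" width="19.689" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-10-7" x="284.051" y="25.600" width="16.798" height="12.800" fill="#1b9e77" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-6-8" x="393.807" y="25.600" width="7.484" height="12.800" fill="#e6ab02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-5-9" x="409.361" y="25.600" width="4.720" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-3-10" x="434.341" y="25.600" width="14.502" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-12-11" x="476.349" y="25.600" width="11.334" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-0-12" x="484.990" y="41.600" width="22.540" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-9-13" x="589.621" y="25.600" width="2.511" height="12.800" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="forward-tes-syn7-1-14" x="688.953" y="25.600" width="7.904" height="12.800" fill="#7570b3" stroke="none" stroke-width="0" opacity="1.000"/>
  </g>
  <g id="layer-simple-repeats">
    <rect id="simple-repeats-syn8-6-15" x="17.242" y="64.000" width="2.875" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-2-16" x="88.649" y="64.000" width="0.507" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-8-17" x="110.001" y="64.000" width="0.847" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-3-18" x="150.156" y="64.000" width="0.792" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-4-19" x="206.562" y="64.000" width="0.475" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-0-20" x="262.176" y="64.000" width="2.392" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-9-21" x="367.045" y="64.000" width="3.073" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-7-22" x="490.914" y="64.000" width="2.495" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-1-23" x="691.076" y="64.000" width="2.170" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="simple-repeats-syn8-5-24" x="725.369" y="64.000" width="0.467" height="8.000" fill="#000000" stroke="none" stroke-width="0" opacity="1.000"/>
  </g>
  <g id="layer-reverse-tes">
    <rect id="reverse-tes-syn9-7-25" x="52.558" y="81.600" width="11.920" height="12.800" fill="#7570b3" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-11-26" x="173.947" y="81.600" width="18.010" height="12.800" fill="#1b9e77" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-10-27" x="210.118" y="81.600" width="21.360" height="12.800" fill="#d95f02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-4-28" x="219.123" y="97.600" width="23.008" height="12.800" fill="#e6ab02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-13-29" x="257.187" y="81.600" width="7.912" height="12.800" fill="#1b9e77" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-6-30" x="291.678" y="81.600" width="14.763" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-8-31" x="301.982" y="97.600" width="1.703" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-2-32" x="379.258" y="81.600" width="18.176" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-9-33" x="594.452" y="81.600" width="17.939" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-12-34" x="612.129" y="97.600" width="14.383" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-3-35" x="618.109" y="81.600" width="9.314" height="12.800" fill="#e6ab02" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-0-36" x="683.726" y="81.600" width="10.930" height="12.800" fill="#1b9e77" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-5-37" x="707.850" y="81.600" width="20.925" height="12.800" fill="#e7298a" stroke="none" stroke-width="0" opacity="1.000"/>
    <rect id="reverse-tes-syn9-1-38" x="708.951" y="97.600" width="21.883" height="12.800" fill="#66a61e" stroke="none" stroke-width="0" opacity="1.000"/>
  </g>
</svg>
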