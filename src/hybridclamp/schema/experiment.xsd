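<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">

  <xs:complexType name="paramList">
    <xs:sequence>
      <xs:element name="param" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:attribute name="name" type="xs:string" use="required"/>
          <xs:attribute name="value" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="preset" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="synapseType">
    <xs:complexContent>
      <xs:extension base="paramList">
        <xs:attribute name="direction" use="required">
          <xs:simpleType>
            <xs:restriction base="xs:string">
              <xs:enumeration value="model_to_live"/>
              <xs:enumeration value="live_to_model"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:attribute>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:element name="hybrid_experiment">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="timing">
          <xs:complexType>
            <xs:attribute name="fs" type="xs:double" use="required"/>
            <xs:attribute name="pre_s" type="xs:double" use="required"/>
            <xs:attribute name="coupled_s" type="xs:double" use="required"/>
            <xs:attribute name="post_s" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="neuron" type="paramList"/>
        <xs:element name="synapse" type="synapseType" minOccurs="2" maxOccurs="2"/>
        <xs:element name="integrator">
          <xs:complexType>
            <xs:attribute name="method" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="euler"/>
                  <xs:enumeration value="heun"/>
                  <xs:enumeration value="rk4"/>
                  <xs:enumeration value="rk65"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
          </xs:complexType>
        </xs:element>
        <xs:element name="calibration">
          <xs:complexType>
            <xs:attribute name="target_burst" type="xs:string" use="required"/>
            <xs:attribute name="online_refresh" type="xs:boolean"/>
            <xs:attribute name="frac_on" type="xs:double" use="required"/>
            <xs:attribute name="frac_off" type="xs:double" use="required"/>
            <xs:attribute name="min_gap_s" type="xs:double" use="required"/>
            <xs:attribute name="drift_compensation" type="xs:boolean" use="required"/>
            <xs:attribute name="drift_window_s" type="xs:double" use="required"/>
            <xs:attribute name="drift_alpha" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="scaling">
          <xs:complexType>
            <xs:attribute name="input_factor" type="xs:double" use="required"/>
            <xs:attribute name="nA_per_V" type="xs:double" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="preparation">
          <xs:complexType>
            <xs:attribute name="preset" type="xs:string" use="required"/>
            <xs:attribute name="period_s" type="xs:double" use="required"/>
            <xs:attribute name="range_min" type="xs:double" use="required"/>
            <xs:attribute name="range_max" type="xs:double" use="required"/>
            <xs:attribute name="noise_sd" type="xs:double" use="required"/>
            <xs:attribute name="drift" type="xs:double" use="required"/>
            <xs:attribute name="replay_path" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="seeds">
          <xs:complexType>
            <xs:attribute name="master" type="xs:integer" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="output" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="dir" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
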