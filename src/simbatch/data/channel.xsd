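<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the synthetic ion-channel description format: a channel with
     named gates, each carrying exponential forward (alpha) and reverse
     (beta) rate constants A (1/ms) and k (mV). -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="channel">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="gate" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="rate" minOccurs="2" maxOccurs="2">
                <xs:complexType>
                  <xs:attribute name="kind" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="alpha"/>
                        <xs:enumeration value="beta"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="A" type="xs:string" use="required"/>
                  <xs:attribute name="k" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="instances" type="xs:positiveInteger"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="leak" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="conductance" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="species" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
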