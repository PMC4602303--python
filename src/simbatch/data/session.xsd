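<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for the XML session format: one complete session = one SimSet
     (inline vectors or a SimSpec file reference) + a simulator type + a
     machine set + user notification info + file locations. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="session">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="simtype">
          <xs:complexType>
            <xs:attribute name="key" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="simset">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="vector" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="p" type="xs:string"
                                minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="simid" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="file" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="machineset">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="machine" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="machine_type" type="xs:string"
                                use="required"/>
                  <xs:attribute name="name" type="xs:string"/>
                  <xs:attribute name="address" type="xs:string"/>
                  <xs:attribute name="num_simulators"
                                type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="work_dir" type="xs:string"
                                use="required"/>
                  <xs:attribute name="queue" type="xs:string"/>
                  <xs:attribute name="wall_time" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="simulator" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="option" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="user" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="notify" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="address" type="xs:string"
                                use="required"/>
                  <xs:attribute name="events" type="xs:string"/>
                  <xs:attribute name="scope" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="locations">
          <xs:complexType>
            <xs:attribute name="root" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
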